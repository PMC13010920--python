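"""Solvent accessibility of guanine N2 in nucleosome structures.

The exocyclic N2 amino group of guanine sits on the minor-groove face of
the G:C base pair and is the principal site of bulky-adduct formation.
Inside a nucleosome the minor groove alternately faces the histone
octamer (minor-in) or solvent (minor-out) with the ~10.2 bp helical
repeat, so N2 accessibility is expected to oscillate with rotational
setting.  This module computes per-atom solvent-accessible surface area
(SASA) by the Shrake-Rupley method and compares N2 SASA between
minor-in and minor-out guanines with a Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .periodicity import RotationalConfig, classify_rotational

#: default van der Waals radii (Angstrom)
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
}

DNA_RESIDUES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    # legacy single-letter nucleotide residue names
    "A": "A", "C": "C", "G": "G", "T": "T",
}


@dataclass
class StructureModel:
    """First model of a structure: coordinates, radii and DNA indexing.

    ``res_id`` holds the author residue sequence number, which in the
    nucleosome crystal structures used here numbers DNA nucleotides by
    dyad-relative position.
    """

    coords: np.ndarray  # (n, 3) Angstrom
    radii: np.ndarray  # (n,)
    elements: np.ndarray
    atom_names: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def guanine_n2_indices(self) -> np.ndarray:
        is_g = np.isin(self.res_names, [r for r, b in DNA_RESIDUES.items() if b == "G"])
        return np.flatnonzero(is_g & (self.atom_names == "N2"))


def parse_structure(
    path, radii: Mapping[str, float] = VDW_RADII
) -> StructureModel:
    """Load ATOM/HETATM records of the first model of a PDB file.

    Radii are assigned per element from a configurable table; an atom
    whose element is missing from the table is an error.  Guanine
    residues lacking an N2 atom are dropped with a warning.
    """
    import warnings

    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    elements = np.array([e.capitalize() for e in atoms.element])
    unknown = sorted(set(elements) - set(radii))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    model = StructureModel(
        coords=np.asarray(atoms.coord, dtype=float),
        radii=np.array([radii[e] for e in elements]),
        elements=elements,
        atom_names=np.asarray(atoms.atom_name),
        res_names=np.asarray(atoms.res_name),
        chain_ids=np.asarray(atoms.chain_id),
        res_ids=np.asarray(atoms.res_id),
    )
    # drop guanine residues without exactly one N2 atom
    keep = np.ones(model.n_atoms, dtype=bool)
    g_names = [r for r, b in DNA_RESIDUES.items() if b == "G"]
    res_keys = list(zip(model.chain_ids, model.res_ids, model.res_names))
    for key in set(k for k in res_keys if k[2] in g_names):
        members = [i for i, k in enumerate(res_keys) if k == key]
        n2 = [i for i in members if model.atom_names[i] == "N2"]
        if len(n2) != 1:
            warnings.warn(f"guanine residue {key} has {len(n2)} N2 atoms; excluded")
            keep[members] = False
    if not keep.all():
        model = StructureModel(
            model.coords[keep], model.radii[keep], model.elements[keep],
            model.atom_names[keep], model.res_names[keep],
            model.chain_ids[keep], model.res_ids[keep],
        )
    return model


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points by the golden-angle spiral."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + math.sqrt(5)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into a structure-intrinsic frame.

    Axes are the principal axes of the coordinate covariance, with each
    axis sign fixed by the third moment of the projections (falling
    back to the largest-magnitude projection on near-symmetric axes).
    Computing occlusion in this frame makes the fixed test-point sphere
    rotate with the structure, so SASA is exactly invariant under rigid
    rotation/translation of the input.
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) < 2:
        return centered
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    proj = centered @ axes
    for k in range(3):
        skew = (proj[:, k] ** 3).sum()
        scale = np.abs(proj[:, k]).max() ** 3 + 1e-300
        if abs(skew) / scale > 1e-8:
            sign = np.sign(skew)
        else:
            sign = np.sign(proj[np.argmax(np.abs(proj[:, k])), k]) or 1.0
        axes[:, k] *= sign
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return centered @ axes


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    atom_indices: np.ndarray | None = None,
    canonical: bool = True,
) -> np.ndarray:
    """Per-atom SASA (Angstrom^2) by the Shrake-Rupley method.

    Test points are distributed on each atom's solvent-expanded sphere
    (radius r + probe); a point is accessible iff it lies outside every
    neighbor's expanded sphere.  SASA = accessible fraction x sphere
    area.  ``atom_indices`` restricts the computation (others get NaN).
    With ``canonical`` (default) occlusion is evaluated in a canonical
    structure-intrinsic frame, so the result does not depend on the
    input's rigid placement; with ``canonical=False`` the test-point
    sphere keeps the input frame, making occlusion point-wise nested
    when atoms are added.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    coords = np.asarray(coords, dtype=float)
    if canonical:
        coords = _canonical_frame(coords)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    targets = np.arange(n) if atom_indices is None else np.asarray(atom_indices)
    out = np.full(n, np.nan)
    for i in targets:
        ri = expanded[i]
        neighbors = [
            j for j in tree.query_ball_point(coords[i], ri + expanded.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]
        ]
        pts = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[j] ** 2
        out[i] = accessible.mean() * 4 * np.pi * ri**2
    return out


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with two-sided p.

    Exact p by enumeration of the null U distribution when
    n_a * n_b <= 400 and there are no ties; otherwise normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = pd.Series(combined).rank(method="average").to_numpy()
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and na * nb <= 400:
        p = _exact_two_sided_p(int(round(u_a)), na, nb)
    else:
        _, counts = np.unique(combined, return_counts=True)
        n = na + nb
        tie_term = (counts**3 - counts).sum()
        sigma2 = na * nb / 12 * ((n**3 - n - tie_term) / (n * (n - 1)))
        if sigma2 <= 0:
            return float(u_a), 1.0
        z = (abs(u_a - na * nb / 2) - 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2 * norm.sf(max(z, 0.0)))
    return float(u_a), float(p)


def _u_distribution(na: int, nb: int) -> np.ndarray:
    """Counts of arrangements per U value under the null (no ties).

    U counts (a, b) pairs with a > b.  Recurrence on the last item of the
    interleaving: c(u; m, j) = c(u - j; m - 1, j) + c(u; m, j - 1)
    (an arrangement of m a's and j b's ends with an 'a' beating all j b's,
    or with a 'b' contributing nothing).
    """
    max_u = na * nb
    # prev[m] = distribution of U for (m a's, j-1 b's)
    prev = [np.zeros(max_u + 1) for _ in range(na + 1)]
    for m in range(na + 1):
        prev[m][0] = 1.0  # j = 0: U is always 0
    for j in range(1, nb + 1):
        cur = [np.zeros(max_u + 1) for _ in range(na + 1)]
        cur[0][0] = 1.0
        for m in range(1, na + 1):
            cur[m][j:] = cur[m - 1][:-j] if j > 0 else cur[m - 1]
            cur[m] = cur[m] + prev[m]
        prev = cur
    return prev[na]


def _exact_two_sided_p(u: int, na: int, nb: int) -> float:
    dist = _u_distribution(na, nb)
    total = dist.sum()
    mean = na * nb / 2
    dev = abs(u - mean)
    us = np.arange(na * nb + 1)
    p = dist[np.abs(us - mean) >= dev - 1e-9].sum() / total
    return min(1.0, float(p))


@dataclass
class SasaGroupComparison:
    minor_in: np.ndarray  # SASA_N2 values, Angstrom^2
    minor_out: np.ndarray
    median_in: float
    median_out: float
    median_ratio: float  # out / in
    u_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n_minor_in": int(self.minor_in.size),
            "n_minor_out": int(self.minor_out.size),
            "median_in": self.median_in,
            "median_out": self.median_out,
            "median_ratio_out_over_in": self.median_ratio,
            "U": self.u_statistic,
            "p_two_sided": self.p_value,
        }


def compare_rotational_sasa(
    model: StructureModel,
    config: RotationalConfig | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaGroupComparison:
    """Compare guanine N2 SASA between minor-in and minor-out positions.

    Each guanine's N2 SASA is assigned a rotational label from its
    dyad-relative nucleotide index (the structure's DNA residue number);
    transition-labeled guanines are excluded.  Reports group medians,
    their out/in ratio, and the Mann-Whitney two-sided test.
    """
    if config is None:
        config = RotationalConfig(core_half_width=10_000)
    n2 = model.guanine_n2_indices()
    if n2.size == 0:
        raise ValueError("structure contains no guanine N2 atoms")
    sasa = shrake_rupley_sasa(
        model.coords, model.radii, probe_radius, n_points, atom_indices=n2
    )[n2]
    labels = classify_rotational(
        model.res_ids[n2].astype(float), config, check_core=False
    )
    vals_in = sasa[labels == "minor_in"]
    vals_out = sasa[labels == "minor_out"]
    if vals_in.size < 3 or vals_out.size < 3:
        raise ValueError("fewer than 3 guanines in a rotational group")
    med_in = float(np.median(vals_in))
    med_out = float(np.median(vals_out))
    u, p = mann_whitney(vals_out, vals_in)
    ratio = med_out / med_in if med_in > 0 else float("inf")
    return SasaGroupComparison(vals_in, vals_out, med_in, med_out, ratio, u, p)
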