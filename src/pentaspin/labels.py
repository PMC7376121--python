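"""In-silico spin labelling and oligomer peak analysis.

The nitroxide label is modelled by a simplified accessible-volume approach:
candidate label midpoints are sampled uniformly in a spherical shell around
the attachment residue's Cβ (tether geometry of an MTSSL-type side chain) and
rejected when they clash with protein heavy atoms. Only the midpoint cloud
statistics feed the predicted distance distributions, which is the quantity
compared with DEER recoveries. "Tight" van der Waals restraints map to a
0.25 nm clash cutoff, "loose" to 0.20 nm (documented constants).

``detect_peaks`` analyses any distance distribution for oligomer-consistent
peak structure: for a C5 ring, the nearest/next-nearest distance ratio D2/D1
must be near 2 cos(36°) ≈ 1.618.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import DistanceDistribution, PipelineError

__all__ = [
    "LabelCloud",
    "PeakReport",
    "read_structure",
    "attach_label",
    "cloud_distance_distribution",
    "oligomer_predicted_distributions",
    "detect_peaks",
    "PENTAMER_RATIO_RANGE",
]

#: clash cutoffs (nm) for the van der Waals restraint presets
CLASH_CUTOFFS_NM = {"tight": 0.25, "loose": 0.20}
#: label-midpoint tether shell around Cβ, nm
TETHER_MIN_NM = 0.4
TETHER_MAX_NM = 1.0
#: acceptance window for a pentamer-consistent D2/D1 ratio
PENTAMER_RATIO_RANGE = (1.55, 1.70)

ANGSTROM_TO_NM = 0.1


def read_structure(pdb_file):
    """Parse a PDB file into a Bio.PDB structure with coordinates in nm.

    Only heavy atoms are retained (hydrogens, waters and heteroatoms are
    excluded); for altlocs the highest-occupancy position survives (the
    Bio.PDB default). Coordinates are converted Å -> nm in place.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", pdb_file)
    except (PDBConstructionException, ValueError) as exc:
        raise PipelineError(f"{pdb_file}: malformed PDB: {exc}") from exc
    n_atoms = 0
    for model in structure:
        for chain in model:
            for residue in list(chain):
                # hetfield != ' ' marks waters and heteroatoms
                if residue.id[0] != " ":
                    chain.detach_child(residue.id)
                    continue
                for atom in list(residue):
                    if atom.element == "H":
                        residue.detach_child(atom.id)
                        continue
                    atom.coord = atom.coord * ANGSTROM_TO_NM
                    n_atoms += 1
    if n_atoms == 0:
        raise PipelineError(f"{pdb_file}: no heavy protein atoms parsed")
    return structure


def _heavy_atom_coords(structure, exclude_site: tuple[str, int] | None = None) -> np.ndarray:
    coords = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if exclude_site is not None and (chain.id, residue.id[1]) == exclude_site:
                    continue
                for atom in residue:
                    coords.append(atom.coord)
        break  # first model only
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def _residue(structure, site: tuple[str, int]):
    chain_id, resnum = site
    for model in structure:
        for chain in model:
            if chain.id != chain_id:
                continue
            for residue in chain:
                if residue.id[1] == resnum:
                    return residue
        break
    raise PipelineError(f"site {chain_id}{resnum} not found in structure")


def _local_frame(residue) -> np.ndarray:
    """Orthonormal frame from the residue's own atoms (columns e1, e2, e3),
    so that label sampling is equivariant under rigid motions of the model."""
    names = [a.get_id() for a in residue]
    coords = {a.get_id(): np.asarray(a.coord, dtype=float) for a in residue}
    ref = None
    for triple in (("N", "CA", "CB"), ("N", "CA", "C"), ("N", "CA", "O")):
        if all(n in names for n in triple):
            ref = [coords[n] for n in triple]
            break
    if ref is None:
        return np.eye(3)
    v1 = ref[2] - ref[1]
    v2 = ref[0] - ref[1]
    e1 = v1 / max(np.linalg.norm(v1), 1e-9)
    v2 = v2 - (v2 @ e1) * e1
    e2 = v2 / max(np.linalg.norm(v2), 1e-9)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _attachment_point(structure, site: tuple[str, int]) -> np.ndarray:
    chain_id, resnum = site
    for model in structure:
        for chain in model:
            if chain.id != chain_id:
                continue
            for residue in chain:
                if residue.id[1] == resnum:
                    if "CB" in residue:
                        return np.asarray(residue["CB"].coord, dtype=float)
                    if "CA" in residue:  # Gly: offset along N->CA
                        ca = np.asarray(residue["CA"].coord, dtype=float)
                        if "N" in residue:
                            n = np.asarray(residue["N"].coord, dtype=float)
                            direction = ca - n
                            direction /= max(np.linalg.norm(direction), 1e-9)
                            return ca + 0.15 * direction
                        return ca
                    raise PipelineError(
                        f"residue {chain_id}{resnum} has no backbone CB/CA atom"
                    )
        break
    raise PipelineError(f"site {chain_id}{resnum} not found in structure")


@dataclass
class LabelCloud:
    """Sterically allowed label-midpoint positions for one site (nm)."""

    chain: str
    resnum: int
    points: np.ndarray  # (m, 3)
    n_attempted: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def survival_fraction(self) -> float:
        return len(self.points) / self.n_attempted if self.n_attempted else 0.0

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def attach_label(
    structure,
    site: tuple[str, int],
    n_samples: int = 2000,
    tether_max: float = TETHER_MAX_NM,
    clash_cutoff: float | str = "tight",
    seed: int | None = None,
    tether_min: float = TETHER_MIN_NM,
) -> LabelCloud:
    """Sample an accessible-volume label cloud at ``site`` = (chain, resnum).

    Candidate midpoints are drawn uniformly in the spherical shell
    [tether_min, tether_max] nm around the residue's Cβ and rejected when any
    retained heavy atom (the labelled residue excluded) lies closer than
    ``clash_cutoff`` — either a number in nm or one of the presets
    ``'tight'`` (0.25 nm) / ``'loose'`` (0.20 nm). Deterministic given seed.
    """
    if isinstance(clash_cutoff, str):
        try:
            clash_cutoff = CLASH_CUTOFFS_NM[clash_cutoff]
        except KeyError:
            raise PipelineError(
                f"unknown clash preset {clash_cutoff!r}; use {sorted(CLASH_CUTOFFS_NM)}"
            ) from None
    if not 0 < tether_min < tether_max:
        raise PipelineError("need 0 < tether_min < tether_max")
    anchor = _attachment_point(structure, site)
    frame = _local_frame(_residue(structure, site))
    rng = np.random.default_rng(seed)
    # uniform in a shell: direction uniform on the sphere, radius ~ r^2;
    # offsets live in the residue's local frame so a rigid motion of the
    # model moves every cloud identically (fixed seed)
    u = rng.normal(size=(n_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = (rng.uniform(tether_min**3, tether_max**3, size=n_samples)) ** (1.0 / 3.0)
    candidates = anchor + (u * radii[:, None]) @ frame.T
    obstacles = _heavy_atom_coords(structure, exclude_site=site)
    if len(obstacles):
        tree = cKDTree(obstacles)
        dmin, _ = tree.query(candidates, k=1)
        keep = dmin >= clash_cutoff
    else:
        keep = np.ones(n_samples, dtype=bool)
    points = candidates[keep]
    if len(points) == 0:
        raise PipelineError(
            f"no sterically allowed label position at {site}; "
            f"try a looser clash cutoff (< {clash_cutoff} nm)"
        )
    return LabelCloud(chain=site[0], resnum=site[1], points=points, n_attempted=n_samples)


def cloud_distance_distribution(
    cloud_a: LabelCloud,
    cloud_b: LabelCloud,
    r_grid: np.ndarray,
) -> DistanceDistribution:
    """Normalised histogram of all inter-cloud point-pair distances."""
    if cloud_a is cloud_b:
        raise PipelineError("cannot build a pair distribution of a cloud with itself")
    if len(cloud_a.points) == 0 or len(cloud_b.points) == 0:
        raise PipelineError("both clouds must be non-empty")
    r_grid = np.asarray(r_grid, dtype=float)
    dists = cdist(cloud_a.points, cloud_b.points).ravel()
    return _histogram_distribution(dists, r_grid)


def _histogram_distribution(dists: np.ndarray, r_grid: np.ndarray) -> DistanceDistribution:
    dr = r_grid[1] - r_grid[0]
    edges = np.concatenate([r_grid - dr / 2, [r_grid[-1] + dr / 2]])
    outside = (dists < edges[0]) | (dists > edges[-1])
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} of {dists.size} pair distances outside the grid; truncated",
            stacklevel=3,
        )
    counts, _ = np.histogram(dists, bins=edges)
    density = counts.astype(float)
    z = np.trapezoid(density, r_grid)
    if z <= 0:
        raise PipelineError("no pair distance falls on the grid")
    return DistanceDistribution(r_grid, density / z)


def oligomer_predicted_distributions(
    structure,
    resnum: int,
    n_subunits: int = 5,
    r_grid: np.ndarray | None = None,
    n_samples: int = 2000,
    clash_cutoff: float | str = "tight",
    seed: int | None = None,
    **label_kw,
) -> DistanceDistribution:
    """Predicted pooled D1+D2 distribution of a labelled Cn oligomer.

    Labels every chain carrying ``resnum``, then pools the nearest-neighbour
    and next-nearest-neighbour inter-cloud histograms. For a pentamer both
    classes contain 5 pairs, giving equal pooling weight. Extra keyword
    arguments (e.g. ``tether_max``) are passed through to ``attach_label``.
    """
    if r_grid is None:
        from .deer import default_r_grid

        r_grid = default_r_grid()
    chains = []
    for model in structure:
        for chain in model:
            if any(res.id[1] == resnum for res in chain):
                chains.append(chain.id)
        break
    if len(chains) < n_subunits:
        raise PipelineError(
            f"residue {resnum} present in {len(chains)} chains, need {n_subunits}"
        )
    chains = chains[:n_subunits]
    clouds = [
        attach_label(
            structure, (c, resnum), n_samples=n_samples,
            clash_cutoff=clash_cutoff, seed=None if seed is None else seed + i,
            **label_kw,
        )
        for i, c in enumerate(chains)
    ]
    # ring order by angle around the centroid of the cloud centroids
    cents = np.array([c.centroid() for c in clouds])
    center = cents.mean(axis=0)
    rel = cents - center
    # principal plane of the ring
    _, _, vt = np.linalg.svd(rel)
    xy = rel @ vt[:2].T
    order = np.argsort(np.arctan2(xy[:, 1], xy[:, 0]))
    clouds = [clouds[i] for i in order]
    n = len(clouds)
    dists = []
    for sep in (1, 2):
        if sep > n // 2:
            continue
        for i in range(n):
            j = (i + sep) % n
            if sep == n - sep and j < i:
                continue  # diameter counted once for even n
            dists.append(cdist(clouds[i].points, clouds[j].points).ravel())
    return _histogram_distribution(np.concatenate(dists), np.asarray(r_grid, dtype=float))


@dataclass
class PeakReport:
    """Peak structure of a distance distribution."""

    modal_distances: np.ndarray
    weights: np.ndarray
    d2_d1_ratio: float | None
    pentamer_consistent: bool

    def __str__(self) -> str:
        lines = ["peak_nm   weight"]
        for d, w in zip(self.modal_distances, self.weights):
            lines.append(f"{d:7.3f}  {w:7.3f}")
        if self.d2_d1_ratio is not None:
            lines.append(
                f"D2/D1 = {self.d2_d1_ratio:.3f} "
                f"({'consistent' if self.pentamer_consistent else 'inconsistent'} "
                f"with a symmetric pentamer)"
            )
        return "\n".join(lines)


def detect_peaks(pr: DistanceDistribution, min_prominence: float = 0.1) -> PeakReport:
    """Detect peaks of P(r) and test for pentamer-consistent structure.

    Local maxima with prominence >= ``min_prominence`` x the global maximum
    are reported, merged when closer than 2 grid steps. D1 is the smallest
    modal distance and D2 the next; the report flags the distribution
    pentamer-consistent when D2/D1 falls in [1.55, 1.70] (the golden-ratio
    window of a C5 ring). Weights are the integrated density split at the
    minima between adjacent peaks.
    """
    dens = pr.density
    gmax = float(dens.max())
    if gmax <= 0:
        return PeakReport(np.array([]), np.array([]), None, False)
    idx, _ = find_peaks(dens, prominence=min_prominence * gmax)
    # merge peaks closer than 2 grid steps, keeping the taller
    merged: list[int] = []
    for i in idx:
        if merged and i - merged[-1] < 2:
            if dens[i] > dens[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    if not merged:
        return PeakReport(np.array([]), np.array([]), None, False)
    modal = pr.r[merged]
    # split mass at the minima between adjacent peaks
    bounds = [0]
    for a, b in zip(merged[:-1], merged[1:]):
        bounds.append(a + int(np.argmin(dens[a:b + 1])))
    bounds.append(len(dens) - 1)
    weights = np.array(
        [np.trapezoid(dens[lo:hi + 1], pr.r[lo:hi + 1]) for lo, hi in zip(bounds[:-1], bounds[1:])]
    )
    weights = weights / weights.sum()
    ratio = None
    consistent = False
    if len(modal) >= 2:
        ratio = float(modal[1] / modal[0])
        consistent = PENTAMER_RATIO_RANGE[0] <= ratio <= PENTAMER_RATIO_RANGE[1]
    return PeakReport(modal, weights, ratio, consistent)
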