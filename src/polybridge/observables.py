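"""Measurable quantities of simulated trajectories.

Factor clusters (the model's transcription factories), Hi-C-like contact
maps with TAD- and compartment-style summary statistics, the 54-nm
transcription criterion, and the tethered-loop visit profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit as _njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .dynamics import Frame, Trajectory
from .model_core import GenomeString

__all__ = [
    "ClusterSet",
    "ContactMap",
    "TranscriptionProfile",
    "detect_clusters",
    "cluster_size_distribution",
    "mixed_cluster_fraction",
    "bound_factor_flags",
    "fraction_bound_in_clusters",
    "compute_contact_map",
    "tad_strength",
    "compartment_signal",
    "transcription_profile",
    "per_run_transcription_means",
    "tether_visit_profile",
]

#: Default factor-factor clustering cutoff: two touching 30-nm spheres
#: with tolerance.
DEFAULT_CLUSTER_CUTOFF_NM = 60.0
#: Default contact-capture radius, matching the transcription criterion.
DEFAULT_CAPTURE_RADIUS_NM = 54.0
#: Distance below which a bead counts as transcribed by a competent factor.
TRANSCRIPTION_RADIUS_NM = 54.0


@dataclass
class ClusterSet:
    """Partition of the factors of one frame into proximity components."""

    clusters: list[np.ndarray]  # every factor in exactly one component
    cutoff_nm: float
    frame_time: float

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)

    def clusters_ge2(self) -> list[np.ndarray]:
        """Components of size >= 2 — what the model calls clusters."""
        return [c for c in self.clusters if len(c) >= 2]

    def labels(self, n_factors: int) -> np.ndarray:
        lab = np.full(n_factors, -1, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[c] = k
        return lab


@dataclass
class ContactMap:
    """Symmetric bead-by-bead contact frequencies in [0, 1]."""

    matrix: np.ndarray
    capture_radius_nm: float
    n_observations: int
    diagonal: str = "zero"  # convention recorded in metadata

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("contact frequencies must lie in [0, 1]")

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TranscriptionProfile:
    """Per-binding-bead transcription probabilities with run-level SEs."""

    bead_index: np.ndarray
    probability: np.ndarray
    se: np.ndarray
    color: list[str]
    n_runs: int

    def __post_init__(self):
        p = self.probability
        if ((p < -1e-12) | (p > 1 + 1e-12)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if (self.se < 0).any():
            raise ValueError("standard errors must be >= 0")


# ---------------------------------------------------------------------------
# clusters


def detect_clusters(frame: Frame, cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM) -> ClusterSet:
    """Connected components of factors with center distance < cutoff."""
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    m = frame.n_factors
    if m == 0:
        return ClusterSet([], cutoff_nm, frame.time)
    tree = cKDTree(frame.factor_positions)
    # query_pairs(r) uses <=; shrink infinitesimally for a strict '<'
    pairs = tree.query_pairs(r=cutoff_nm * (1.0 - 1e-12), output_type="ndarray")
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
        n_comp, lab = connected_components(g, directed=False)
    else:
        n_comp, lab = m, np.arange(m)
    clusters = [np.flatnonzero(lab == k) for k in range(n_comp)]
    return ClusterSet(clusters, cutoff_nm, frame.time)


def cluster_size_distribution(
    trajectory: Trajectory, cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM
) -> tuple[Counter, float, float]:
    """Histogram of component sizes pooled over frames.

    Returns ``(counts, mean_size, se)`` where the mean component size is
    averaged per frame first and the SE is taken over frames.
    """
    if trajectory.n_frames < 1:
        raise ValueError("need at least one post-equilibration frame")
    counts: Counter = Counter()
    per_frame_mean = []
    for fr in trajectory.frames:
        cs = detect_clusters(fr, cutoff_nm)
        sizes = cs.sizes
        counts.update(sizes.tolist())
        if len(sizes):
            per_frame_mean.append(sizes.mean())
    mean = float(np.mean(per_frame_mean))
    se = float(np.std(per_frame_mean, ddof=1) / np.sqrt(len(per_frame_mean))) if len(per_frame_mean) > 1 else 0.0
    return counts, mean, se


def mixed_cluster_fraction(
    trajectory: Trajectory, cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM
) -> float:
    """Fraction of size>=2 clusters containing more than one factor color.

    With disjoint cognate bead sets, bridging demixes the colors in 3D and
    this fraction stays small.
    """
    colors = np.array(trajectory.frames[0].factor_colors)
    mixed = 0
    total = 0
    for fr in trajectory.frames:
        for c in detect_clusters(fr, cutoff_nm).clusters_ge2():
            total += 1
            if len(set(colors[c])) > 1:
                mixed += 1
    if total == 0:
        return 0.0
    return mixed / total


def bound_factor_flags(frame: Frame, trajectory: Trajectory) -> np.ndarray:
    """Which factors sit within the binding range of a cognate bead.

    Binding is geometric (the attraction is an implicit potential well):
    a factor is bound when its center lies within contact + attraction
    range of a bead carrying its color.  Competence is required.
    """
    string = trajectory.string
    field = trajectory.field
    if field is None:
        raise ValueError("trajectory carries no force field")
    field = field.resolve(string)
    sigma = string.bead_diameter_nm
    colors = np.array(frame.factor_colors)
    comp = np.asarray(frame.binding_competent, dtype=bool)
    bound = np.zeros(frame.n_factors, dtype=bool)
    bead_colors = [b.colors for b in string.beads]
    diam = {sp.color: sp.diameter_nm for sp in trajectory.species}
    for color in set(colors):
        cog = np.array([color in bc for bc in bead_colors])
        if not cog.any():
            continue
        sel = (colors == color) & comp
        if not sel.any():
            continue
        cutoff = (sigma + diam.get(color, sigma)) / 2.0 + field.attraction_range_nm
        tree = cKDTree(frame.bead_positions[cog])
        d, _ = tree.query(frame.factor_positions[sel], distance_upper_bound=cutoff)
        bound[np.flatnonzero(sel)[np.isfinite(d)]] = True
    return bound


def fraction_bound_in_clusters(
    trajectory: Trajectory, cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM
) -> float:
    """Mean over frames of (bound factors in size>=2 clusters) / (bound factors)."""
    vals = []
    for fr in trajectory.frames:
        bound = bound_factor_flags(fr, trajectory)
        nb = bound.sum()
        if nb == 0:
            continue
        lab = detect_clusters(fr, cutoff_nm).labels(fr.n_factors)
        sizes = np.bincount(lab)
        in_cluster = sizes[lab] >= 2
        vals.append((bound & in_cluster).sum() / nb)
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# contact maps


def compute_contact_map(
    trajectories: Trajectory | Iterable[Trajectory],
    capture_radius_nm: float = DEFAULT_CAPTURE_RADIUS_NM,
) -> ContactMap:
    """Fraction of observations with bead centers within the capture radius.

    Observations are pooled over all frames of all given trajectories
    (frames are already post-equilibration).  The diagonal is left at zero.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories or sum(t.n_frames for t in trajectories) < 1:
        raise ValueError("need at least one post-equilibration frame")
    n = trajectories[0].string.n_beads
    counts = np.zeros((n, n))
    n_obs = 0
    for traj in trajectories:
        if traj.string.n_beads != n:
            raise ValueError("all trajectories must share the bead count")
        for fr in traj.frames:
            tree = cKDTree(fr.bead_positions)
            pairs = tree.query_pairs(r=capture_radius_nm, output_type="ndarray")
            if len(pairs):
                counts[pairs[:, 0], pairs[:, 1]] += 1.0
            n_obs += 1
    counts = counts + counts.T
    return ContactMap(counts / n_obs, capture_radius_nm, n_obs)


def _matched_ratio(matrix, in_a, in_b, separations):
    """Sum over separations of matched-mean ratios, weighted by 'a' counts.

    ``in_a(s) -> bool mask over pairs at separation s`` etc.; returns
    (weighted numerator, weighted denominator) of mean_a / mean_b pooled
    over separations present in both classes.
    """
    num = 0.0
    den = 0.0
    used = 0
    for s in separations:
        diag = np.diagonal(matrix, offset=s)
        a = in_a(s)
        b = in_b(s)
        na, nbn = a.sum(), b.sum()
        if na == 0 or nbn == 0:
            continue
        num += na * diag[a].mean()
        den += na * diag[b].mean()
        used += 1
    if used == 0:
        raise ValueError("no separations with pairs in both classes")
    return num, den


def tad_strength(
    cmap: ContactMap, blocks: Sequence[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Separation-matched intra/inter contact ratio per block.

    For each block (half-open bead interval) the mean contact frequency
    among bead pairs inside the block is compared with pairs at the same
    genomic separation that straddle the block boundary, removing the
    overall distance decay.  A TAD-like block scores well above 1.
    """
    n = cmap.n_beads
    spans = sorted(blocks)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("blocks must be disjoint")
    bid = np.full(n, -1, dtype=int)
    for k, (s, e) in enumerate(blocks):
        if not (0 <= s < e <= n):
            raise ValueError(f"block {(s, e)} outside the map")
        if e - s < 2:
            raise ValueError(f"block {(s, e)} shorter than 2 beads")
        bid[s:e] = k

    ratios = {}
    m = cmap.matrix
    for k, (s, e) in enumerate(blocks):
        width = e - s
        seps = range(1, width)
        def intra(sep, k=k):
            return (bid[: n - sep] == k) & (bid[sep:] == k)
        def inter(sep, k=k):
            return (bid[: n - sep] == k) ^ (bid[sep:] == k)
        num, den = _matched_ratio(m, intra, inter, seps)
        ratios[(s, e)] = num / den if den > 0 else np.inf
    return ratios


def compartment_signal(
    cmap: ContactMap, string: GenomeString, min_separation: int = 100
) -> float:
    """Long-range same-color vs different-color contact enrichment.

    Only pairs of colored (binding) beads at genomic separation
    >= ``min_separation`` enter; "same" means the color sets intersect.
    Means are matched separation by separation, so the enrichment of a
    color-blind (shuffled) map is ~1 and bridging compartments score > 1.
    """
    masks = string.color_masks()
    present = {c for b in string.beads for c in b.colors}
    if len(present) < 2:
        raise ValueError("need at least two colors present")
    n = cmap.n_beads
    if min_separation >= n:
        raise ValueError("no pairs beyond the minimum separation")

    def same(s):
        return ((masks[: n - s] & masks[s:]) != 0)

    def diff(s):
        return (masks[: n - s] != 0) & (masks[s:] != 0) & ((masks[: n - s] & masks[s:]) == 0)

    num, den = _matched_ratio(cmap.matrix, same, diff, range(min_separation, n))
    if den == 0:
        return np.inf
    return num / den


# ---------------------------------------------------------------------------
# transcription


def per_run_transcription_means(
    trajectory: Trajectory,
    string: GenomeString | None = None,
    radius_nm: float = TRANSCRIPTION_RADIUS_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-binding-bead fraction of frames satisfying the 54-nm criterion.

    A bead is transcribed in a frame when a binding-competent factor of one
    of its colors lies within ``radius_nm`` of its center.  Returns
    ``(binding_bead_indices, per_bead_mean_over_frames)``.
    """
    string = string or trajectory.string
    idx = string.binding_bead_indices()
    counts = np.zeros(len(idx))
    colors = np.array(trajectory.frames[0].factor_colors) if trajectory.frames else np.array([])
    bead_colors = [string.beads[i].colors for i in idx]
    for fr in trajectory.frames:
        comp = np.asarray(fr.binding_competent, dtype=bool)
        hit = np.zeros(len(idx), dtype=bool)
        for color in {c for bc in bead_colors for c in bc}:
            sel = (colors == color) & comp
            if not sel.any():
                continue
            which = np.array([color in bc for bc in bead_colors])
            tree = cKDTree(fr.factor_positions[sel])
            d, _ = tree.query(fr.bead_positions[idx[which]], distance_upper_bound=radius_nm)
            hit[np.flatnonzero(which)[np.isfinite(d)]] = True
        counts += hit
    nfr = max(trajectory.n_frames, 1)
    return idx, counts / nfr


def transcription_profile(
    ensemble: Sequence[Trajectory],
    string: GenomeString | None = None,
    radius_nm: float = TRANSCRIPTION_RADIUS_NM,
) -> TranscriptionProfile:
    """Ensemble transcription probabilities with run-level standard errors.

    Run-level (not frame-level) means enter the SE because frames within a
    run are autocorrelated.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    string = string or ensemble[0].string
    for t in ensemble:
        if t.string != string:
            raise ValueError("all trajectories must share the genome string")
    idx = string.binding_bead_indices()
    runs = np.empty((len(ensemble), len(idx)))
    for r, traj in enumerate(ensemble):
        _, means = per_run_transcription_means(traj, string, radius_nm)
        runs[r] = means
    prob = runs.mean(0)
    if len(ensemble) > 1:
        se = runs.std(0, ddof=1) / np.sqrt(len(ensemble))
    else:
        se = np.zeros_like(prob)
    color = [",".join(sorted(string.beads[i].colors)) for i in idx]
    return TranscriptionProfile(idx, prob, se, color, len(ensemble))


def transcribed_cluster_association(
    trajectory: Trajectory,
    radius_nm: float = TRANSCRIPTION_RADIUS_NM,
    cluster_cutoff_nm: float = DEFAULT_CLUSTER_CUTOFF_NM,
) -> tuple[float, float]:
    """(conditional, unconditional) cluster membership of transcribing factors.

    The conditional term is, among transcribed (bead, frame) observations,
    the fraction whose nearest transcribing factor sits in a size>=2
    cluster; the unconditional term is the overall fraction of factors in
    such clusters.  Transcription typically happens in a cluster, so the
    conditional fraction is the larger one.
    """
    string = trajectory.string
    idx = string.binding_bead_indices()
    colors = np.array(trajectory.frames[0].factor_colors)
    cond_hits = 0
    cond_total = 0
    unc_in = 0
    unc_total = 0
    bead_colors = [string.beads[i].colors for i in idx]
    for fr in trajectory.frames:
        lab = detect_clusters(fr, cluster_cutoff_nm).labels(fr.n_factors)
        sizes = np.bincount(lab) if len(lab) else np.array([])
        in_cluster = sizes[lab] >= 2 if len(lab) else np.array([], dtype=bool)
        unc_in += int(in_cluster.sum())
        unc_total += fr.n_factors
        comp = np.asarray(fr.binding_competent, dtype=bool)
        for color in {c for bc in bead_colors for c in bc}:
            sel = np.flatnonzero((colors == color) & comp)
            if not len(sel):
                continue
            which = np.array([color in bc for bc in bead_colors])
            tree = cKDTree(fr.factor_positions[sel])
            d, j = tree.query(fr.bead_positions[idx[which]], distance_upper_bound=radius_nm)
            hit = np.isfinite(d)
            cond_total += int(hit.sum())
            cond_hits += int(in_cluster[sel[j[hit]]].sum())
    cond = cond_hits / cond_total if cond_total else 0.0
    unc = unc_in / unc_total if unc_total else 0.0
    return cond, unc


# ---------------------------------------------------------------------------
# tethered loop


def tether_visit_profile(
    loop_kbp: float = 77.0,
    sphere_diameter_nm: float = 75.0,
    n_samples: int = 20000,
    seed: int = 0,
    segment_nm: float = 30.0,
    bp_per_segment: int = 3000,
    shell_nm: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo visit frequencies of a loop tethered to a sphere.

    The loop is a freely-jointed ring of ``segment_nm`` segments (77 kbp at
    3 kb per 30-nm segment gives ~26), anchored at one point of the sphere
    surface, with the sphere an excluded volume.  Crankshaft rotations that
    keep every monomer outside the sphere are the Monte-Carlo moves.
    Returns ``(visit_probability, se)`` per monomer, where a visit means
    lying within ``shell_nm`` of the sphere surface.  The profile is
    mirror-symmetric about the loop midpoint and decreases from the anchors
    to the midpoint: monomers on a short tether visit the sphere's
    neighborhood more often than distant ones.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    K = int(round(loop_kbp * 1000.0 / bp_per_segment))
    if K < 4:
        raise ValueError("loop too short for a ring")
    if K * segment_nm < sphere_diameter_nm:
        raise ValueError("loop contour must exceed the sphere diameter")
    R = sphere_diameter_nm / 2.0

    counts = _tether_mc(K, segment_nm, R, shell_nm, n_samples, seed)
    p = counts / n_samples
    se = np.sqrt(np.clip(p * (1 - p), 0, None) / n_samples)
    return p, se


def _tether_mc(K, seg, R, shell, n_samples, seed):
    return _tether_mc_jit(K, seg, R, shell, n_samples, seed)


@_njit(cache=True)
def _tether_mc_jit(K, seg, R, shell, n_samples, seed):
    np.random.seed(seed)
    # initial planar regular polygon, tangent to the sphere at vertex 0
    rp = seg / (2.0 * np.sin(np.pi / K))
    v = np.empty((K, 3))
    for j in range(K):
        ang = np.pi + 2.0 * np.pi * j / K
        v[j, 0] = (R + rp) + rp * np.cos(ang)
        v[j, 1] = rp * np.sin(ang)
        v[j, 2] = 0.0

    counts = np.zeros(K, dtype=np.int64)
    burn = 200 * K
    thin = K
    total_moves = burn + n_samples * thin
    R2 = R * R
    lim = R + shell

    new = np.empty((K, 3))
    for move in range(total_moves):
        # pick a chord (a, b) not spanning the fixed vertex 0
        a = 1 + int(np.random.random() * (K - 3))
        b = a + 2 + int(np.random.random() * (K - a - 1))
        if b > K - 1:
            b = K - 1
        if b - a < 2:
            continue
        ax = v[b, 0] - v[a, 0]
        ay = v[b, 1] - v[a, 1]
        az = v[b, 2] - v[a, 2]
        an = np.sqrt(ax * ax + ay * ay + az * az)
        if an < 1e-12:
            continue
        ax /= an
        ay /= an
        az /= an
        theta = (np.random.random() * 2.0 - 1.0) * np.pi
        ct = np.cos(theta)
        st = np.sin(theta)
        ok = True
        for j in range(a + 1, b):
            px = v[j, 0] - v[a, 0]
            py = v[j, 1] - v[a, 1]
            pz = v[j, 2] - v[a, 2]
            dot = px * ax + py * ay + pz * az
            # Rodrigues rotation about the unit axis
            cx = ay * pz - az * py
            cy = az * px - ax * pz
            cz = ax * py - ay * px
            qx = px * ct + cx * st + ax * dot * (1.0 - ct)
            qy = py * ct + cy * st + ay * dot * (1.0 - ct)
            qz = pz * ct + cz * st + az * dot * (1.0 - ct)
            nx = v[a, 0] + qx
            ny = v[a, 1] + qy
            nz = v[a, 2] + qz
            if nx * nx + ny * ny + nz * nz < R2:
                ok = False
                break
            new[j, 0] = nx
            new[j, 1] = ny
            new[j, 2] = nz
        if ok:
            for j in range(a + 1, b):
                v[j, 0] = new[j, 0]
                v[j, 1] = new[j, 1]
                v[j, 2] = new[j, 2]
        if move >= burn and (move - burn) % thin == 0:
            for j in range(K):
                r = np.sqrt(v[j, 0] ** 2 + v[j, 1] ** 2 + v[j, 2] ** 2)
                if r <= lim:
                    counts[j] += 1
    return counts
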