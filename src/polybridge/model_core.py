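"""Genome strings, factor species, and chromatin-state annotation.

The simulated chromatin fiber is a string of beads at a fixed genomic
resolution (by default one 30-nm bead per 3 kb).  Each bead carries a
(possibly empty) set of color labels; a diffusing protein "factor" of a
given color binds only to beads carrying that color.  Strings are either
generated synthetically (cognate beads of each color scattered at random,
as in the in-silico eQTL experiment) or derived from a chromatin-state
annotation by binning intervals onto beads.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ParseError

__all__ = [
    "Bead",
    "GenomeString",
    "FactorSpecies",
    "ChromatinStateTrack",
    "generate_random_string",
    "generate_block_string",
    "apply_mutation",
    "beads_from_track",
]

#: Default genomic span of one bead, in bp (30-nm bead = 3 kb).
DEFAULT_BP_PER_BEAD = 3000
#: Default bead diameter, in nm.
DEFAULT_BEAD_DIAMETER_NM = 30.0


@dataclass(frozen=True)
class Bead:
    """One monomer of the fiber.

    Parameters
    ----------
    index
        0-based position along the string.
    colors
        Color labels this bead presents to factors; an empty set means the
        bead is non-binding.  A bead may carry more than one color (e.g. a
        window split between an active and a silent chromatin state), in
        which case it binds factors of every color it carries.
    genomic_span
        Optional ``(chrom, start, end)`` in bp, 0-based half-open.
    """

    index: int
    colors: frozenset[str] = frozenset()
    genomic_span: tuple[str, int, int] | None = None


@dataclass(frozen=True)
class FactorSpecies:
    """A population of identical multivalent binding proteins.

    Binding competence switches stochastically between an active
    ("phosphorylated") and inactive state at first-order rates, modelling
    post-translational modification cycles; the defaults (equal on/off rates
    of 1e-5 per Brownian time, i.e. ~0.001 1/s at the 0.01 s/tauB mapping)
    give a stationary competent fraction of one half.
    """

    color: str
    count: int
    diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM
    specific_affinity_kT: float = 7.0
    nonspecific_affinity_kT: float = 0.0
    switch_off_rate: float = 1e-5  # per Brownian time
    switch_on_rate: float = 1e-5

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"factor count must be >= 0, got {self.count}")
        if self.diameter_nm <= 0:
            raise ValueError("factor diameter must be positive")
        if self.specific_affinity_kT < 0 or self.nonspecific_affinity_kT < 0:
            raise ValueError("affinities must be >= 0 kT")
        if self.switch_off_rate < 0 or self.switch_on_rate < 0:
            raise ValueError("switching rates must be >= 0")

    @property
    def stationary_competent_fraction(self) -> float:
        """Equilibrium probability that a factor is binding-competent."""
        total = self.switch_on_rate + self.switch_off_rate
        if total == 0.0:
            return 1.0
        return self.switch_on_rate / total


class GenomeString:
    """An ordered string of beads with its palette and physical metadata.

    Parameters
    ----------
    beads
        Beads with contiguous 0-based indices.
    palette
        Declared color labels in a fixed order; the order fixes color
        indices in reports and in the simulation engine.  Every bead color
        must belong to the palette.
    bp_per_bead, bead_diameter_nm
        Genomic and physical size of one bead.
    """

    def __init__(
        self,
        beads: Sequence[Bead],
        palette: Sequence[str],
        bp_per_bead: int = DEFAULT_BP_PER_BEAD,
        bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM,
    ):
        beads = list(beads)
        if not beads:
            raise ValueError("a GenomeString needs at least one bead")
        if int(bp_per_bead) <= 0:
            raise ValueError("bp_per_bead must be positive")
        if bead_diameter_nm <= 0:
            raise ValueError("bead_diameter_nm must be positive")
        palette = list(palette)
        if len(set(palette)) != len(palette):
            raise ValueError("palette colors must be unique")
        pal = set(palette)
        for i, b in enumerate(beads):
            if b.index != i:
                raise ValueError(
                    f"bead indices must be 0-based and contiguous; "
                    f"position {i} holds index {b.index}"
                )
            extra = set(b.colors) - pal
            if extra:
                raise ValueError(f"bead {i} carries colors {sorted(extra)} not in palette")
        self.beads: list[Bead] = beads
        self.palette: list[str] = palette
        self.bp_per_bead = int(bp_per_bead)
        self.bead_diameter_nm = float(bead_diameter_nm)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def __len__(self) -> int:
        return len(self.beads)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeString)
            and self.palette == other.palette
            and self.bp_per_bead == other.bp_per_bead
            and self.bead_diameter_nm == other.bead_diameter_nm
            and self.beads == other.beads
        )

    def color_masks(self) -> np.ndarray:
        """Per-bead color bitmasks in palette order (bit ``k`` = palette[k])."""
        if len(self.palette) > 63:
            raise ValueError("at most 63 palette colors supported")
        bit = {c: np.uint64(1 << k) for k, c in enumerate(self.palette)}
        masks = np.zeros(self.n_beads, dtype=np.uint64)
        for i, b in enumerate(self.beads):
            m = np.uint64(0)
            for c in b.colors:
                m |= bit[c]
            masks[i] = m
        return masks

    def binding_bead_indices(self) -> np.ndarray:
        """Indices of beads carrying at least one color."""
        return np.array([b.index for b in self.beads if b.colors], dtype=np.int64)

    def color_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.palette}
        for b in self.beads:
            for c in b.colors:
                counts[c] += 1
        return counts


@dataclass
class ChromatinStateTrack:
    """Interval annotation of chromatin states (BED convention).

    Intervals are ``(chrom, start_bp, end_bp, state_label)``, 0-based
    half-open.  ``state_to_color`` maps a state label to the factor color it
    recruits; states mapping to ``None`` (or absent states) leave beads
    non-binding.
    """

    intervals: list[tuple[str, int, int, str]]
    state_to_color: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        for k, (chrom, start, end, state) in enumerate(self.intervals):
            if start < 0 or start >= end:
                raise ParseError(
                    f"interval {k} ({chrom}:{start}-{end} {state}) must satisfy "
                    f"0 <= start < end",
                    line=k + 1,
                )


def generate_random_string(
    n_beads: int,
    palette: Sequence[str],
    density_per_color: float | Sequence[float],
    seed: int,
    bp_per_bead: int = DEFAULT_BP_PER_BEAD,
    bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM,
) -> GenomeString:
    """Scatter cognate beads of each color at random along a string.

    Each bead is independently assigned at most one color: with probability
    ``density_per_color[k]`` it gets ``palette[k]``, otherwise it stays
    non-binding.  This emulates binding sites for several factor types
    randomly distributed along a wild-type fiber; multi-colored beads arise
    only from annotation binning (:func:`beads_from_track`), never here.

    Deterministic for a given seed.
    """
    if n_beads < 1:
        raise ValueError(f"n_beads must be >= 1, got {n_beads}")
    palette = list(palette)
    if np.isscalar(density_per_color):
        densities = [float(density_per_color)] * len(palette)
    else:
        densities = [float(d) for d in density_per_color]
    if len(densities) != len(palette):
        raise ValueError("need one density per palette color")
    if any(d < 0 for d in densities):
        raise ValueError("densities must be >= 0")
    if sum(densities) > 1.0 + 1e-12:
        raise ValueError(f"densities sum to {sum(densities):.4f} > 1")

    rng = np.random.default_rng(seed)
    # one categorical draw per bead: colors 0..K-1, or K = non-binding
    probs = np.array(densities + [1.0 - sum(densities)])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    draws = rng.choice(len(probs), size=n_beads, p=probs)
    beads = []
    for i in range(n_beads):
        k = draws[i]
        colors = frozenset() if k == len(palette) else frozenset({palette[k]})
        span = ("synthetic", i * bp_per_bead, (i + 1) * bp_per_bead)
        beads.append(Bead(index=i, colors=colors, genomic_span=span))
    return GenomeString(beads, palette, bp_per_bead, bead_diameter_nm)


def generate_block_string(
    n_beads: int,
    block_beads: int,
    block_colors: Sequence[str | None],
    density_within_block: float = 1.0,
    seed: int = 0,
    bp_per_bead: int = DEFAULT_BP_PER_BEAD,
    bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM,
) -> GenomeString:
    """A string of fixed-size blocks with colors cycling over blocks.

    Emulates domain-structured chromatin annotations (active/silent blocks):
    block ``k`` uses ``block_colors[k % len(block_colors)]``; ``None`` makes
    a non-binding block.  Within a colored block each bead carries the color
    independently with probability ``density_within_block``.  Because the
    cognate sites of different colors are separated along the sequence,
    bridging factors of different colors form spatially distinct clusters.
    """
    if n_beads < 1 or block_beads < 1:
        raise ValueError("n_beads and block_beads must be >= 1")
    if not (0.0 <= density_within_block <= 1.0):
        raise ValueError("density_within_block must be in [0, 1]")
    if not block_colors:
        raise ValueError("need at least one block color (None allowed)")
    rng = np.random.default_rng(seed)
    palette = list(dict.fromkeys(c for c in block_colors if c is not None))
    beads = []
    for i in range(n_beads):
        color = block_colors[(i // block_beads) % len(block_colors)]
        colors: frozenset[str] = frozenset()
        if color is not None and rng.random() < density_within_block:
            colors = frozenset({color})
        span = ("synthetic", i * bp_per_bead, (i + 1) * bp_per_bead)
        beads.append(Bead(index=i, colors=colors, genomic_span=span))
    return GenomeString(beads, palette, bp_per_bead, bead_diameter_nm)


def apply_mutation(string: GenomeString, bead_index: int) -> GenomeString:
    """Return a mutant string in which one bead has lost all binding colors.

    Models a regulatory variant (an eQTL) that abolishes factor binding at a
    single site; every other bead is untouched and the input string is not
    modified.  Mutating an already non-binding bead is a no-op and emits a
    warning.
    """
    if not (0 <= bead_index < string.n_beads):
        raise ValueError(
            f"bead_index {bead_index} out of range for a {string.n_beads}-bead string"
        )
    old = string.beads[bead_index]
    if not old.colors:
        warnings.warn(
            f"bead {bead_index} is already non-binding; mutation is a no-op",
            UserWarning,
            stacklevel=2,
        )
    beads = list(string.beads)
    beads[bead_index] = replace(old, colors=frozenset())
    return GenomeString(
        beads, list(string.palette), string.bp_per_bead, string.bead_diameter_nm
    )


def beads_from_track(
    track: ChromatinStateTrack,
    region: tuple[str, int, int],
    bp_per_bead: int = DEFAULT_BP_PER_BEAD,
    occupancy_threshold: float = 0.5,
    bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM,
    palette: Sequence[str] | None = None,
) -> GenomeString:
    """Bin a chromatin-state annotation onto beads.

    The region is tiled into windows of ``bp_per_bead`` (the last, possibly
    partial, window is kept).  A state colors a bead when its intervals
    cover at least ``occupancy_threshold`` of the window, so a window split
    exactly half/half between two states yields a doubly-colored bead at the
    default threshold of 0.5.  States without a color mapping leave beads
    non-binding.

    Coloring is invariant to interval order and to splitting intervals into
    abutting pieces, because only total bp coverage per state per window
    matters.
    """
    chrom, start, end = region
    if end - start < bp_per_bead:
        raise ValueError("region must span at least one bead")
    if not (0.0 < occupancy_threshold <= 1.0):
        raise ValueError("occupancy_threshold must be in (0, 1]")

    edges = list(range(start, end, bp_per_bead)) + [end]
    n_beads = len(edges) - 1

    # total bp coverage per (window, state); overlapping same-state intervals
    # are clipped per interval, so duplicated intervals double-count -- the
    # track is expected to be a partition, as chromatin-state tracks are.
    coverage: list[dict[str, int]] = [dict() for _ in range(n_beads)]
    for chrom_i, s, e, state in track.intervals:
        if chrom_i != chrom:
            continue
        s = max(s, start)
        e = min(e, end)
        if s >= e:
            continue
        first = (s - start) // bp_per_bead
        last = min((e - 1 - start) // bp_per_bead, n_beads - 1)
        for w in range(first, last + 1):
            ov = min(e, edges[w + 1]) - max(s, edges[w])
            if ov > 0:
                coverage[w][state] = coverage[w].get(state, 0) + ov

    colors_per_bead: list[frozenset[str]] = []
    seen_colors: list[str] = []
    for w in range(n_beads):
        width = edges[w + 1] - edges[w]
        cols = set()
        for state, bp in sorted(coverage[w].items()):
            color = track.state_to_color.get(state)
            if color is None:
                continue
            if bp / width >= occupancy_threshold - 1e-12:
                cols.add(color)
                if color not in seen_colors:
                    seen_colors.append(color)
        colors_per_bead.append(frozenset(cols))

    if palette is None:
        # stable palette: mapping order first, then any extras as seen
        palette = [c for c in dict.fromkeys(track.state_to_color.values()) if c is not None]
        palette += [c for c in seen_colors if c not in palette]
    beads = [
        Bead(index=w, colors=colors_per_bead[w], genomic_span=(chrom, edges[w], edges[w + 1]))
        for w in range(n_beads)
    ]
    return GenomeString(beads, palette, bp_per_bead, bead_diameter_nm)


def deep_copy_string(string: GenomeString) -> GenomeString:
    """An independent copy (beads are immutable, so this is shallow-safe)."""
    return copy.deepcopy(string)
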