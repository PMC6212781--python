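"""Plain-text file formats and the run manifest.

Everything is desk-inspectable text: BED for chromatin-state tracks, TSV
for genome strings, contact maps, profiles and reports, extended-XYZ-style
frames for trajectories, and JSON for manifests.  Coordinates follow the
BED convention (0-based, half-open) throughout.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Frame, Trajectory
from .errors import IntegrityError, ParseError
from .model_core import Bead, ChromatinStateTrack, GenomeString
from .observables import ContactMap, TranscriptionProfile

__all__ = [
    "read_state_track",
    "write_state_track",
    "read_genome_string",
    "write_genome_string",
    "read_contact_map",
    "write_contact_map",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_transcription_profile",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# BED state tracks


def read_state_track(path, state_to_color=None) -> ChromatinStateTrack:
    """Read a 4+-column BED file of chromatin states.

    Columns: chrom, start, end, state name; extra columns (score, strand,
    ...) are ignored.  Malformed lines raise :class:`ParseError` carrying
    the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"line {lineno}: expected at least 4 columns, got {len(parts)}",
                    line=lineno,
                )
            chrom, s, e, state = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric coordinates {s!r}, {e!r}", line=lineno
                ) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"line {lineno}: need 0 <= start < end, got {start}, {end}",
                    line=lineno,
                )
            intervals.append((chrom, start, end, state))
    return ChromatinStateTrack(intervals, state_to_color or {})


def write_state_track(track: ChromatinStateTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, state in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")


# ---------------------------------------------------------------------------
# genome strings


def write_genome_string(string: GenomeString, path) -> None:
    """TSV: bead_index, colors (comma-joined, '.' if none), chrom, start, end."""
    with open(path, "w") as fh:
        fh.write(f"# bp_per_bead={string.bp_per_bead}\n")
        fh.write(f"# bead_diameter_nm={string.bead_diameter_nm}\n")
        fh.write(f"# palette={','.join(string.palette)}\n")
        fh.write("bead_index\tcolors\tchrom\tstart\tend\n")
        for b in string.beads:
            colors = ",".join(sorted(b.colors)) if b.colors else "."
            chrom, s, e = b.genomic_span if b.genomic_span else (".", -1, -1)
            fh.write(f"{b.index}\t{colors}\t{chrom}\t{s}\t{e}\n")


def read_genome_string(path) -> GenomeString:
    meta = {}
    beads = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    header = lines[body_start].strip().split("\t")
    if header[:2] != ["bead_index", "colors"]:
        raise ParseError("missing genome-string header line", line=body_start + 1)
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 5:
            raise ParseError(f"line {lineno}: expected 5 columns", line=lineno)
        idx = int(parts[0])
        colors = frozenset() if parts[1] == "." else frozenset(parts[1].split(","))
        span = None
        if parts[2] != ".":
            span = (parts[2], int(parts[3]), int(parts[4]))
        beads.append(Bead(index=idx, colors=colors, genomic_span=span))
    palette = [c for c in meta.get("palette", "").split(",") if c]
    return GenomeString(
        beads,
        palette,
        bp_per_bead=int(meta.get("bp_per_bead", 3000)),
        bead_diameter_nm=float(meta.get("bead_diameter_nm", 30.0)),
    )


# ---------------------------------------------------------------------------
# contact maps


def write_contact_map(cmap: ContactMap, path) -> None:
    """Dense TSV with a '#'-prefixed metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# capture_radius_nm={cmap.capture_radius_nm}\n")
        fh.write(f"# n_observations={cmap.n_observations}\n")
        fh.write(f"# diagonal={cmap.diagonal}\n")
        np.savetxt(fh, cmap.matrix, fmt="%.10g", delimiter="\t")


def read_contact_map(path) -> ContactMap:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if matrix.shape[0] != matrix.shape[1]:
        raise IntegrityError(f"contact matrix is {matrix.shape}, not square")
    if not np.allclose(matrix, matrix.T, rtol=1e-9, atol=1e-12):
        raise IntegrityError("contact matrix is not symmetric")
    try:
        return ContactMap(
            matrix=matrix,
            capture_radius_nm=float(meta["capture_radius_nm"]),
            n_observations=int(meta["n_observations"]),
            diagonal=meta.get("diagonal", "zero"),
        )
    except KeyError as e:
        raise IntegrityError(f"contact-map header missing {e}") from None


# ---------------------------------------------------------------------------
# trajectories (extended-XYZ-style)


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """One block per frame: count, comment with time, then per-particle rows.

    Rows are ``kind color competent x y z`` with kind B (bead) or F
    (factor), coordinates in nm.
    """
    with open(path, "w") as fh:
        for fr in traj.frames:
            P = fr.n_beads + fr.n_factors
            fh.write(f"{P}\n")
            fh.write(f"time_tauB={fr.time:.6f} n_beads={fr.n_beads}\n")
            for i in range(fr.n_beads):
                x, y, z = fr.bead_positions[i]
                colors = ",".join(sorted(traj.string.beads[i].colors)) or "."
                fh.write(f"B\t{colors}\t1\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")
            for k in range(fr.n_factors):
                x, y, z = fr.factor_positions[k]
                comp = 1 if fr.binding_competent[k] else 0
                fh.write(f"F\t{fr.factor_colors[k]}\t{comp}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")


def read_trajectory_xyz(path) -> list[Frame]:
    """Frames only (geometry and flags); the system metadata is not stored."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        P = int(lines[i])
        comment = lines[i + 1]
        fields = dict(kv.split("=") for kv in comment.split())
        t = float(fields["time_tauB"])
        nb = int(fields["n_beads"])
        rows = lines[i + 2 : i + 2 + P]
        bead_pos = np.empty((nb, 3))
        fac_pos = np.empty((P - nb, 3))
        fac_colors = []
        comp = np.zeros(P - nb, dtype=bool)
        for r, row in enumerate(rows):
            kind, color, c, x, y, z = row.split("\t")
            if r < nb:
                bead_pos[r] = (float(x), float(y), float(z))
            else:
                fac_pos[r - nb] = (float(x), float(y), float(z))
                fac_colors.append(color)
                comp[r - nb] = c == "1"
        frames.append(
            Frame(
                time=t,
                bead_positions=bead_pos,
                factor_positions=fac_pos,
                factor_colors=fac_colors,
                binding_competent=comp,
            )
        )
        i += 2 + P
    return frames


def write_transcription_profile(profile: TranscriptionProfile, path) -> None:
    df = pd.DataFrame(
        {
            "bead_index": profile.bead_index,
            "color": profile.color,
            "probability": profile.probability,
            "se": profile.se,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# n_runs={profile.n_runs}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifests


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's deterministic outputs."""

    tool: str
    version: str
    master_seed: int
    config_hash: str
    per_run_seeds: list[int] = dc_field(default_factory=list)
    input_digests: dict = dc_field(default_factory=dict)
    parameters: dict = dc_field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        d = asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
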