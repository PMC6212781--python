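"""Overdamped Brownian dynamics of the fiber plus diffusing factors.

Units
-----
Lengths are in nm, energies in kT, and time in Brownian times (tauB), the
time for a reference bead (the fiber bead) to diffuse the square of its own
diameter: ``D_ref = sigma^2 / tauB`` with ``sigma`` the bead diameter.
Other particles diffuse with ``D ~ 1/diameter`` (Stokes scaling).  The
physical mapping ``tauB ~ 0.01 s`` follows from equating the default
phosphorylation switching rate of 1e-5/tauB with ~0.001 1/s.

The integrator is the Euler–Maruyama scheme for overdamped Langevin
dynamics: ``x <- x + (D/kT) F dt + sqrt(2 D dt) xi`` with unit-variance
Gaussian ``xi`` per coordinate.  Pair forces are soft (capped), so the only
runtime stability check needed is on the deterministic drift: a drift
exceeding ``ForceField.max_drift_nm`` in one step aborts the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import StabilityError
from .model_core import FactorSpecies, GenomeString

__all__ = [
    "ForceField",
    "SimulationConfig",
    "Frame",
    "Trajectory",
    "compute_forces",
    "potential_energy",
    "bd_step",
    "switch_states",
    "run_simulation",
]

logger = logging.getLogger("polybridge")

_CHUNK_STEPS = 1024


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters, all in nm / kT units.

    ``None`` fields are resolved against the system geometry by
    :meth:`resolve`: the bond rest length defaults to the bead diameter,
    the bond constant to 185 kT/sigma^2, and the attraction range to
    1.8x the bead radius beyond contact.  ``specific_attraction_depth``
    normally stays ``None`` so each factor species contributes its own
    affinity; setting it overrides every species.

    The bond constant and the default timestep (0.002 tauB) are chosen
    together: the stiffest normal mode of a harmonic chain under explicit
    overdamped integration has eigenvalue 4 k, so stability requires
    ``4 k D dt < 2``; 185 kT/sigma^2 at dt = 0.002 sits at ~1.5 with room
    for contact stiffness on top, and bond fluctuations are small enough
    (sd ~ 0.073 sigma) that bonds essentially never stretch past 1.5x
    their rest length.
    """

    bond_spring_constant: float | None = None  # kT/nm^2
    bond_rest_length: float | None = None  # nm
    excluded_volume_strength: float = 50.0  # kT at full overlap
    specific_attraction_depth: float | None = None  # kT; None -> per species
    attraction_range_nm: float | None = None  # beyond contact
    bending_rigidity: float = 0.0  # kT (harmonic-cosine)
    confinement_radius_nm: float | None = None
    confinement_spring_constant: float = 0.1667  # kT/nm^2
    force_cap_kT_per_nm: float = 1.0
    max_drift_nm: float | None = None  # None -> two bead diameters
    neighbor_skin_nm: float | None = None  # None -> two bead diameters

    def resolve(self, string: GenomeString) -> "ForceField":
        """Fill ``None`` fields from the string's bead diameter."""
        sigma = string.bead_diameter_nm
        return replace(
            self,
            bond_spring_constant=(
                self.bond_spring_constant
                if self.bond_spring_constant is not None
                else 185.0 / sigma**2
            ),
            bond_rest_length=(
                self.bond_rest_length if self.bond_rest_length is not None else sigma
            ),
            attraction_range_nm=(
                self.attraction_range_nm
                if self.attraction_range_nm is not None
                else 1.8 * (sigma / 2.0)
            ),
            max_drift_nm=(
                self.max_drift_nm if self.max_drift_nm is not None else 2.0 * sigma
            ),
            neighbor_skin_nm=(
                self.neighbor_skin_nm if self.neighbor_skin_nm is not None else 2.0 * sigma
            ),
        )

    def __post_init__(self):
        if self.excluded_volume_strength < 0:
            raise ValueError("excluded_volume_strength must be >= 0")
        if self.attraction_range_nm is not None and self.attraction_range_nm <= 0:
            raise ValueError("attraction range must exceed the contact distance")
        if self.bending_rigidity < 0:
            raise ValueError("bending_rigidity must be >= 0")


def confinement_radius_for_volume_fraction(
    string: GenomeString, species: Sequence[FactorSpecies], volume_fraction: float = 0.02
) -> float:
    """Radius of the sphere at which all particles occupy the given volume fraction.

    The default of 2% corresponds to a dilute chromatin solution (a fiber
    segment plus its soluble factors inside a territory-sized region), the
    regime in which factor co-localization reflects bridging rather than
    crowding.
    """
    if not (0 < volume_fraction < 0.74):
        raise ValueError("volume_fraction must be in (0, 0.74)")
    v = string.n_beads * (np.pi / 6.0) * string.bead_diameter_nm**3
    for sp in species:
        v += sp.count * (np.pi / 6.0) * sp.diameter_nm**3
    return float((3.0 * v / (4.0 * np.pi * volume_fraction)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length, discretization and reproducibility parameters."""

    n_steps: int
    seed: int
    equilibration_steps: int = 0
    frame_interval: int = 1000
    timestep_tauB: float = 0.002
    temperature_kT: float = 1.0
    brownian_time_seconds: float = 0.01

    def __post_init__(self):
        if self.timestep_tauB <= 0:
            raise ValueError("timestep must be positive")
        if not (self.n_steps >= self.equilibration_steps >= 0):
            raise ValueError("need n_steps >= equilibration_steps >= 0")
        if self.frame_interval < 1:
            raise ValueError("frame_interval must be >= 1")

    def rate_per_second(self, rate_per_tauB: float) -> float:
        """Convert a rate in 1/tauB to 1/s via the physical time mapping."""
        return rate_per_tauB / self.brownian_time_seconds


@dataclass
class Frame:
    """One snapshot: bead and factor coordinates plus competence flags."""

    time: float  # tauB
    bead_positions: np.ndarray  # (nb, 3) nm
    factor_positions: np.ndarray  # (nf, 3) nm
    factor_colors: list[str]
    binding_competent: np.ndarray  # (nf,) bool

    @property
    def n_beads(self) -> int:
        return self.bead_positions.shape[0]

    @property
    def n_factors(self) -> int:
        return self.factor_positions.shape[0]

    def all_positions(self) -> np.ndarray:
        return np.vstack([self.bead_positions, self.factor_positions])


@dataclass
class Trajectory:
    """Time-ordered frames with the system that produced them."""

    frames: list[Frame]
    string: GenomeString
    species: list[FactorSpecies]
    config: SimulationConfig
    field: ForceField | None = None

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def config_hash(self) -> str:
        return config_hash(self.string, self.species, self.config, self.field)


def config_hash(
    string: GenomeString,
    species: Sequence[FactorSpecies],
    config: SimulationConfig,
    field: ForceField | None,
    include_seed: bool = False,
) -> str:
    """Digest of everything that defines an ensemble arm except the seed.

    Two ensembles are comparable when their hashes agree apart from the
    mutated bead, so the string enters via palette/size/metadata and the
    per-color bead counts are deliberately left out.
    """
    payload = {
        "n_beads": string.n_beads,
        "palette": string.palette,
        "bp_per_bead": string.bp_per_bead,
        "bead_diameter_nm": string.bead_diameter_nm,
        "species": [
            [sp.color, sp.count, sp.diameter_nm, sp.specific_affinity_kT,
             sp.nonspecific_affinity_kT, sp.switch_off_rate, sp.switch_on_rate]
            for sp in species
        ],
        "config": [
            config.n_steps, config.equilibration_steps, config.frame_interval,
            config.timestep_tauB, config.temperature_kT, config.brownian_time_seconds,
        ]
        + ([config.seed] if include_seed else []),
        "field": None if field is None else [
            field.bond_spring_constant, field.bond_rest_length,
            field.excluded_volume_strength, field.specific_attraction_depth,
            field.attraction_range_nm, field.bending_rigidity,
            field.confinement_radius_nm, field.force_cap_kT_per_nm,
        ],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# system assembly


class _System:
    """Flat-array view of (string, species) for the kernels."""

    def __init__(
        self,
        string: GenomeString,
        species: Sequence[FactorSpecies],
        field: ForceField,
    ):
        self.string = string
        self.species = list(species)
        self.field = field.resolve(string)
        nb = string.n_beads
        nf = sum(sp.count for sp in species)
        self.nb, self.nf = nb, nf

        sigma = string.bead_diameter_nm
        self.radius = np.empty(nb + nf)
        self.radius[:nb] = sigma / 2.0
        self.bead_mask = string.color_masks()

        bit_of = {c: np.uint64(1 << k) for k, c in enumerate(string.palette)}
        self.factor_bit = np.zeros(nf, dtype=np.uint64)
        self.eps_spec = np.zeros(nf)
        self.eps_ns = np.zeros(nf)
        self.factor_species_idx = np.zeros(nf, dtype=np.int64)
        self.factor_colors: list[str] = []
        k = 0
        for si, sp in enumerate(self.species):
            for _ in range(sp.count):
                self.radius[nb + k] = sp.diameter_nm / 2.0
                self.factor_bit[k] = bit_of.get(sp.color, np.uint64(0))
                depth = (
                    self.field.specific_attraction_depth
                    if self.field.specific_attraction_depth is not None
                    else sp.specific_affinity_kT
                )
                self.eps_spec[k] = depth
                self.eps_ns[k] = sp.nonspecific_affinity_kT
                self.factor_species_idx[k] = si
                self.factor_colors.append(sp.color)
                k += 1

        # Stokes scaling of diffusion constants: D_ref = sigma^2 per tauB
        self.D = sigma**2 * (sigma / (2.0 * self.radius))

        f = self.field
        self.r_cut_max = float(2.0 * self.radius.max() + f.attraction_range_nm)

    def kernel_args(self):
        f = self.field
        return dict(
            radius=self.radius,
            nb=self.nb,
            bead_mask=self.bead_mask,
            factor_bit=self.factor_bit,
            eps_spec=self.eps_spec,
            eps_ns=self.eps_ns,
            k_bond=f.bond_spring_constant,
            r0_bond=f.bond_rest_length,
            e0_rep=f.excluded_volume_strength,
            f_cap=f.force_cap_kT_per_nm,
            attr_w=f.attraction_range_nm,
            kappa=f.bending_rigidity,
            r_conf=f.confinement_radius_nm or 0.0,
            k_conf=f.confinement_spring_constant,
        )


def _frame_system(frame: Frame, string: GenomeString, species: Sequence[FactorSpecies],
                  field: ForceField) -> tuple[_System, np.ndarray, np.ndarray]:
    sys = _System(string, species, field)
    if frame.n_beads != sys.nb or frame.n_factors != sys.nf:
        raise ValueError(
            f"frame has {frame.n_beads} beads / {frame.n_factors} factors, "
            f"system expects {sys.nb} / {sys.nf}"
        )
    pos = np.ascontiguousarray(frame.all_positions(), dtype=np.float64)
    comp = np.ascontiguousarray(frame.binding_competent, dtype=np.uint8)
    return sys, pos, comp


# ---------------------------------------------------------------------------
# reference (numpy) force/energy path — slow, used by the step-level API and
# as an independent check on the numba kernels


def _pair_tables(sys: _System, competent: np.ndarray):
    """Per-(particle, particle) attraction depth; vectorized helper."""
    nb, nf = sys.nb, sys.nf
    eps = np.zeros((nb + nf, nb + nf))
    cognate = (sys.bead_mask[:, None] & sys.factor_bit[None, :]) != 0
    depth = np.where(cognate, sys.eps_spec[None, :], sys.eps_ns[None, :])
    depth = depth * competent[None, :].astype(float)
    eps[:nb, nb:] = depth
    eps[nb:, :nb] = depth.T
    return eps


def _repulsion_energy(r, contact, e0, f_cap):
    """Capped soft-core potential matching the kernel's capped force."""
    fr_at = 2.0 * e0 / contact  # slope scale
    # radius below which the force saturates at f_cap
    r_star = contact - f_cap * contact**2 / (2.0 * e0)
    u_quad = e0 * (1.0 - r / contact) ** 2
    u_star = e0 * (1.0 - r_star / contact) ** 2
    u = np.where(r >= r_star, u_quad, u_star + f_cap * (r_star - r))
    return np.where(r < contact, u, 0.0), fr_at


def pair_potential(r, contact, e0, f_cap, eps, attr_w):
    """Scalar pair potential (nm, kT) of the model; vectorized over ``r``."""
    r = np.asarray(r, dtype=float)
    u_rep, _ = _repulsion_energy(r, contact, e0, f_cap)
    u = u_rep.copy()
    inside = r < contact
    well = (r >= contact) & (r < contact + attr_w)
    u = u - eps * inside
    theta = (np.pi / 2.0) * (r - contact) / attr_w
    u = np.where(well, u - eps * np.cos(theta) ** 2, u)
    return u


def compute_forces(
    frame: Frame,
    string: GenomeString,
    species: Sequence[FactorSpecies],
    field: ForceField | None = None,
) -> np.ndarray:
    """Forces (kT/nm) on every particle: beads first, then factors.

    Pure-numpy brute-force evaluation of the same force laws the simulation
    kernel uses; intended for analysis and for small systems.  Pairwise
    contributions are antisymmetric, so internal forces sum to zero in the
    absence of confinement.
    """
    field = (field or ForceField()).resolve(string)
    sys, pos, comp = _frame_system(frame, string, species, field)
    P = sys.nb + sys.nf
    f = np.zeros((P, 3))

    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(r, np.inf)
    contact = sys.radius[:, None] + sys.radius[None, :]
    eps = _pair_tables(sys, comp)
    w = field.attraction_range_nm

    # repulsion (capped)
    fr = 2.0 * field.excluded_volume_strength * (contact - r) / contact**2
    fr = np.clip(fr, None, field.force_cap_kT_per_nm)
    fr = np.where(r < contact, fr, 0.0)
    # attraction well
    well = (r >= contact) & (r < contact + w) & (eps > 0)
    arg = np.clip(r - contact, 0.0, w)  # keeps sin() finite off the well
    fa = -eps * np.pi / (2.0 * w) * np.sin(np.pi * arg / w)
    fa = np.where(well, fa, 0.0)
    fmag = fr + fa  # positive = repulsive
    with np.errstate(invalid="ignore"):
        f += np.nansum((fmag / r)[:, :, None] * d, axis=1)

    # bonds
    nb = sys.nb
    if nb > 1:
        db = pos[: nb - 1] - pos[1:nb]
        rb = np.linalg.norm(db, axis=1)
        s = -field.bond_spring_constant * (rb - field.bond_rest_length) / rb
        fb = s[:, None] * db
        f[: nb - 1] += fb
        f[1:nb] -= fb

    # bending
    kappa = field.bending_rigidity
    if kappa > 0 and nb > 2:
        b1 = pos[1 : nb - 1] - pos[: nb - 2]
        b2 = pos[2:nb] - pos[1 : nb - 1]
        n1 = np.linalg.norm(b1, axis=1)
        n2 = np.linalg.norm(b2, axis=1)
        u = b1 / n1[:, None]
        v = b2 / n2[:, None]
        ct = (u * v).sum(1)
        fa_ = -kappa * (v - ct[:, None] * u) / n1[:, None]
        fc_ = kappa * (u - ct[:, None] * v) / n2[:, None]
        f[: nb - 2] += fa_
        f[2:nb] += fc_
        f[1 : nb - 1] -= fa_ + fc_

    # confinement
    if field.confinement_radius_nm:
        rr = np.linalg.norm(pos, axis=1)
        lim = field.confinement_radius_nm - sys.radius
        out = rr > lim
        if out.any():
            s = -field.confinement_spring_constant * (rr[out] - lim[out]) / rr[out]
            f[out] += s[:, None] * pos[out]

    if not np.isfinite(f).all():
        raise FloatingPointError("non-finite force encountered")
    return f


def potential_energy(
    frame: Frame,
    string: GenomeString,
    species: Sequence[FactorSpecies],
    field: ForceField | None = None,
) -> float:
    """Total potential energy (kT) consistent with :func:`compute_forces`."""
    field = (field or ForceField()).resolve(string)
    sys, pos, comp = _frame_system(frame, string, species, field)
    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(r.shape[0], 1)
    r_ij = r[iu]
    contact = (sys.radius[:, None] + sys.radius[None, :])[iu]
    eps = _pair_tables(sys, comp)[iu]
    u = pair_potential(r_ij, contact, sys.field.excluded_volume_strength,
                       sys.field.force_cap_kT_per_nm, eps, sys.field.attraction_range_nm)
    # pair_potential applies eps inside contact as well; for eps==0 pairs only
    # the repulsion survives.
    total = float(u.sum())

    nb = sys.nb
    if nb > 1:
        rb = np.linalg.norm(pos[: nb - 1] - pos[1:nb], axis=1)
        total += float(
            0.5 * field.bond_spring_constant * ((rb - field.bond_rest_length) ** 2).sum()
        )
    if field.bending_rigidity > 0 and nb > 2:
        b1 = pos[1 : nb - 1] - pos[: nb - 2]
        b2 = pos[2:nb] - pos[1 : nb - 1]
        ct = (b1 * b2).sum(1) / (np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1))
        total += float(field.bending_rigidity * (1.0 - ct).sum())
    if field.confinement_radius_nm:
        rr = np.linalg.norm(pos, axis=1)
        over = np.clip(rr - (field.confinement_radius_nm - sys.radius), 0.0, None)
        total += float(0.5 * field.confinement_spring_constant * (over**2).sum())
    return total


# ---------------------------------------------------------------------------
# step-level API


def bd_step(
    frame: Frame,
    string: GenomeString,
    species: Sequence[FactorSpecies],
    field: ForceField | None = None,
    dt: float = 0.01,
    rng: np.random.Generator | None = None,
    kT: float = 1.0,
) -> Frame:
    """One Euler–Maruyama update of every particle.

    ``rng=None`` disables the noise term, which turns the update into a
    steepest-descent step (used for deterministic energy-relaxation checks).
    ``dt=0`` returns an identical frame.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    field = (field or ForceField()).resolve(string)
    sys, pos, _ = _frame_system(frame, string, species, field)
    if dt == 0:
        return _copy_frame(frame)
    f = compute_forces(frame, string, species, field)
    drift = (sys.D / kT * dt)[:, None] * f
    dmax = np.linalg.norm(drift, axis=1).max()
    if dmax > field.max_drift_nm:
        bad = int(np.linalg.norm(drift, axis=1).argmax())
        raise StabilityError(
            f"drift {dmax:.1f} nm exceeds {field.max_drift_nm:.1f} nm "
            f"for particle {bad}",
            particle=bad,
        )
    new = pos + drift
    if rng is not None:
        new = new + rng.standard_normal(pos.shape) * np.sqrt(2.0 * sys.D * dt)[:, None]
    nb = sys.nb
    return Frame(
        time=frame.time + dt,
        bead_positions=new[:nb],
        factor_positions=new[nb:],
        factor_colors=list(frame.factor_colors),
        binding_competent=frame.binding_competent.copy(),
    )


def switch_states(
    frame: Frame,
    species: Sequence[FactorSpecies],
    dt: float,
    rng: np.random.Generator,
) -> Frame:
    """First-order stochastic switching of binding competence.

    Each competent factor loses competence with probability
    ``switch_off_rate * dt`` and each incompetent one regains it with
    probability ``switch_on_rate * dt``, independently.
    """
    off = np.concatenate([[sp.switch_off_rate] * sp.count for sp in species]) if species else np.array([])
    on = np.concatenate([[sp.switch_on_rate] * sp.count for sp in species]) if species else np.array([])
    if len(off) != frame.n_factors:
        raise ValueError("species counts do not match the frame's factors")
    p_off = off * dt
    p_on = on * dt
    if (p_off >= 1).any() or (p_on >= 1).any():
        raise ValueError("rate*dt must be < 1 for the first-order approximation")
    u = rng.random(frame.n_factors)
    comp = frame.binding_competent.astype(bool)
    flip = np.where(comp, u < p_off, u < p_on)
    out = _copy_frame(frame)
    out.binding_competent = comp ^ flip
    return out


def _copy_frame(frame: Frame) -> Frame:
    return Frame(
        time=frame.time,
        bead_positions=frame.bead_positions.copy(),
        factor_positions=frame.factor_positions.copy(),
        factor_colors=list(frame.factor_colors),
        binding_competent=np.asarray(frame.binding_competent).copy(),
    )


# ---------------------------------------------------------------------------
# initial conformations


def initial_conformation(
    sys: _System, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk fiber with overlap rejection; factors scattered around it.

    The walk grows bond by bond, rejecting placements that overlap earlier
    beads by more than 20% of contact or leave the confinement sphere; after
    a bounded number of tries the placement is accepted anyway (the capped
    soft-core forces relax residual overlaps during equilibration).
    """
    nb, nf = sys.nb, sys.nf
    sigma = sys.string.bead_diameter_nm
    r_conf = sys.field.confinement_radius_nm
    pos = np.zeros((nb + nf, 3))

    def inside(x, rad):
        return r_conf is None or np.linalg.norm(x) < r_conf - rad

    bead_r = sigma / 2.0
    for i in range(1, nb):
        placed = False
        for _ in range(60):
            v = rng.standard_normal(3)
            v *= sys.field.bond_rest_length / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if not inside(cand, bead_r):
                continue
            lo = max(0, i - 400)  # locality: distant beads rarely collide
            d2 = ((pos[lo : i - 1] - cand) ** 2).sum(1) if i - 1 > lo else np.empty(0)
            if d2.size and (d2 < (0.8 * sigma) ** 2).any():
                continue
            pos[i] = cand
            placed = True
            break
        if not placed:
            # bias back toward the center; residual overlaps relax under the
            # capped soft-core forces during equilibration
            v = -pos[i - 1]
            n = np.linalg.norm(v)
            v = v / n * sys.field.bond_rest_length if n > 1e-9 else np.array(
                [sys.field.bond_rest_length, 0.0, 0.0]
            )
            pos[i] = pos[i - 1] + v

    span = (
        (r_conf - sys.radius[nb:].max()) if r_conf is not None
        else max(np.abs(pos[:nb]).max() + 2 * sigma, 2 * sigma)
    )
    for k in range(nf):
        rad = sys.radius[nb + k]
        for _ in range(60):
            cand = rng.uniform(-span, span, 3)
            if np.linalg.norm(cand) > span:
                continue
            d2 = ((pos[: nb + k] - cand) ** 2).sum(1)
            if (d2 < (0.8 * (rad + sys.radius[: nb + k].max())) ** 2).any():
                continue
            break
        pos[nb + k] = cand
    return pos


def _switch_events(
    sys: _System, n_steps: int, dt: float, rng: np.random.Generator,
    competent0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-sampled competence flip times (exact two-state Markov chain).

    Per-step flip probabilities are geometric, so dwell times are sampled
    directly; the kernel just applies the flips at the recorded steps.
    """
    steps: list[int] = []
    facs: list[int] = []
    for k in range(sys.nf):
        sp = sys.species[sys.factor_species_idx[k]]
        p = {True: sp.switch_off_rate * dt, False: sp.switch_on_rate * dt}
        if max(p.values()) >= 0.1:
            raise ValueError("rate*dt must be < 0.1 for first-order switching")
        state = bool(competent0[k])
        t = 0
        while True:
            pk = p[state]
            if pk <= 0:
                break
            t += int(rng.geometric(pk))
            if t > n_steps:
                break
            steps.append(t)
            facs.append(k)
            state = not state
    order = np.argsort(np.array(steps, dtype=np.int64), kind="stable")
    return (
        np.array(steps, dtype=np.int64)[order],
        np.array(facs, dtype=np.int64)[order],
    )


# ---------------------------------------------------------------------------
# the main driver


def run_simulation(
    string: GenomeString,
    species: Sequence[FactorSpecies],
    field: ForceField | None = None,
    config: SimulationConfig | None = None,
    pinned_beads: Sequence[int] = (),
    initial_positions: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the system and return post-equilibration frames.

    Frames are recorded every ``config.frame_interval`` steps once
    ``config.equilibration_steps`` have passed.  Particle count is conserved
    by construction; a deterministic drift larger than the force field's
    ``max_drift_nm`` raises :class:`StabilityError` with the step number.
    ``pinned_beads`` are held fixed (zero mobility), which is how a single
    binding site is tethered in the two-particle calibration runs.
    """
    if config is None:
        raise ValueError("a SimulationConfig is required")
    field = (field or ForceField()).resolve(string)
    sys = _System(string, species, field)
    P = sys.nb + sys.nf
    dt = config.timestep_tauB
    rng = np.random.default_rng(config.seed)

    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=np.float64)
        if pos.shape != (P, 3):
            raise ValueError(f"initial_positions must be {(P, 3)}")
    else:
        pos = initial_conformation(sys, rng)

    competent = np.zeros(sys.nf, dtype=np.uint8)
    for k in range(sys.nf):
        sp = sys.species[sys.factor_species_idx[k]]
        competent[k] = 1 if rng.random() < sp.stationary_competent_fraction else 0

    sw_steps, sw_fac = _switch_events(sys, config.n_steps, dt, rng, competent)

    eq = config.equilibration_steps
    fi = config.frame_interval
    n_frames = (config.n_steps - eq) // fi
    frame_steps = eq + fi * np.arange(1, n_frames + 1, dtype=np.int64)
    frames_pos = np.empty((n_frames, P, 3))
    frames_comp = np.empty((n_frames, sys.nf), dtype=np.uint8)

    mobility_dt = sys.D / config.temperature_kT * dt
    # uniform noise in the fused kernel: sqrt(12) restores unit variance
    noise_scale = np.sqrt(2.0 * sys.D * dt) * np.sqrt(12.0)
    if len(pinned_beads):
        pinned = np.asarray(pinned_beads, dtype=np.int64)
        mobility_dt = mobility_dt.copy()
        noise_scale = noise_scale.copy()
        mobility_dt[pinned] = 0.0
        noise_scale[pinned] = 0.0

    cap = max(64 * P, 4096)

    def _alloc(c):
        return (
            np.empty(c, dtype=np.int32),
            np.empty(c, dtype=np.int32),
            np.empty(c),
            np.empty(c),
            np.empty(c),
            np.empty(c, dtype=np.int32),
            np.empty(c),
            np.empty(c, dtype=np.int32),
            np.empty(c, dtype=np.int32),
            np.empty(c),
            np.empty(c),
            np.empty(c),
            np.empty(c, dtype=np.int32),
        )

    (pair_i, pair_j, pair_contact, pair_cut2, pair_eps, pair_fa, pair_near2,
     near_i, near_j, near_contact, near_cut2, near_eps, near_fa) = _alloc(cap)
    build_pos = np.empty_like(pos)
    near_pos = np.empty_like(pos)
    fbuf = np.empty_like(pos)
    state = np.zeros(8, dtype=np.int64)
    state[_kernels.S_NEEDS_REBUILD] = 1

    ka = sys.kernel_args()
    chash = config_hash(string, species, config, field)
    logger.info(
        "run_simulation: %d beads, %d factors, %d steps, seed=%d, config=%s",
        sys.nb, sys.nf, config.n_steps, config.seed, chash,
    )

    done = 0
    while done < config.n_steps:
        chunk = min(_CHUNK_STEPS, config.n_steps - done)
        noise = rng.random((chunk, P, 3), dtype=np.float32)
        off = 0
        while off < chunk:
            code = _kernels._run_chunk(
                pos, build_pos, near_pos, ka["radius"], mobility_dt, noise_scale,
                ka["nb"], ka["bead_mask"], ka["factor_bit"], ka["eps_spec"],
                ka["eps_ns"], competent,
                ka["k_bond"], ka["r0_bond"], ka["e0_rep"], ka["f_cap"],
                ka["attr_w"], ka["kappa"], ka["r_conf"], ka["k_conf"],
                field.neighbor_skin_nm, _kernels.SKIN_INNER_NM, field.max_drift_nm,
                noise[off:], done + off, sw_steps, sw_fac,
                frame_steps, frames_pos, frames_comp,
                pair_i, pair_j, pair_contact, pair_cut2, pair_eps, pair_fa,
                pair_near2, near_i, near_j, near_contact, near_cut2, near_eps,
                near_fa, state, fbuf,
            )
            advanced = int(state[_kernels.S_STEPS_DONE])
            if code == _kernels.PAIR_OVERFLOW:
                off += advanced
                cap *= 2
                (pair_i, pair_j, pair_contact, pair_cut2, pair_eps, pair_fa,
                 pair_near2, near_i, near_j, near_contact, near_cut2,
                 near_eps, near_fa) = _alloc(cap)
                state[_kernels.S_NEEDS_REBUILD] = 1
                continue
            if code == _kernels.STABILITY_ABORT:
                step = done + off + advanced
                bad = int(state[_kernels.S_BAD_PARTICLE])
                raise StabilityError(
                    f"deterministic drift exceeded {field.max_drift_nm:.1f} nm "
                    f"at step {step} (particle {bad})",
                    particle=bad,
                    step=step,
                )
            off += advanced
        done += chunk

    logger.info("run_simulation: completed %d steps, %d frames", done, n_frames)

    frames = []
    for k in range(n_frames):
        frames.append(
            Frame(
                time=float(frame_steps[k]) * dt,
                bead_positions=frames_pos[k, : sys.nb].copy(),
                factor_positions=frames_pos[k, sys.nb :].copy(),
                factor_colors=list(sys.factor_colors),
                binding_competent=frames_comp[k].astype(bool),
            )
        )
    return Trajectory(frames=frames, string=string, species=list(species),
                      config=config, field=field)
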