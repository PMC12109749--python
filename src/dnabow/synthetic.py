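"""Synthetic bent-duplex trajectories, melting curves and emission spectra.

Every generator is a pure function of its spec (including the RNG seed) and
returns known ground truth alongside the data, so each analysis stage can be
validated by parameter recovery instead of archived MD runs or lab data.

The trajectory generator emulates, geometrically, the features the analyses
measure: per-residue coordinate fluctuations (isotropic Gaussian, applied
rigidly within a residue so intra-residue geometry stays exact),
two-state telegraph base-pair opening with end-fraying defaults,
a soft end-to-end constraint standing in for the virtual spring between the
C6 atoms of residues 2 and 29, and diffusing Na+/Mg2+/Cl- ions with
exponential bound residence on phosphate groups.  It does not integrate
forces: no solvent, no energetics, no sequence-dependent helical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .builder import DuplexBuildSpec, build_bent_duplex, pair_frames
from .core import (
    DUPLEX_LENGTH,
    ION_SPECIES,
    Topology,
    Trajectory,
    infer_element,
)
from .melting import MeltingCurve
from .fret import ACCEPTOR_NM, DONOR_NM, EmissionSpectrum
from .refgeom import ideal_base_pair

__all__ = [
    "SpringSpec",
    "IonSpec",
    "TrajectorySimSpec",
    "MeltingSimSpec",
    "SpectrumSimSpec",
    "IonGroundTruth",
    "GroundTruth",
    "default_sigma_profile",
    "default_open_prob_profile",
    "simulate_trajectory",
    "simulate_melting_curve",
    "simulate_spectrum",
]

DEFAULT_BOX = (90.0, 120.0, 90.0)  # A, echoing the solvation-box proportions


def default_sigma_profile(base: float = 0.35, end: float = 0.6) -> np.ndarray:
    """Per-pair fluctuation std (A): elevated at the duplex ends (fraying)."""
    sigma = np.full(DUPLEX_LENGTH, base)
    sigma[[0, 1, DUPLEX_LENGTH - 2, DUPLEX_LENGTH - 1]] = end
    return sigma


def default_open_prob_profile(
    internal: float = 0.02, end: float = 0.30, near_ten: float = 0.10
) -> np.ndarray:
    """Stationary open probabilities: large at both ends, a bump near pair 10.

    The shape mirrors the qualitative per-residue picture for the bent
    sensor without stabilising ions (frayed ends, a weak spot around residue
    10); the magnitudes are illustrative, not fitted.
    """
    p = np.full(DUPLEX_LENGTH, internal)
    p[[0, DUPLEX_LENGTH - 1]] = end
    p[[1, DUPLEX_LENGTH - 2]] = end / 2
    p[[8, 9, 10]] = near_ten
    return p


@dataclass(frozen=True)
class SpringSpec:
    """Soft geometric stand-in for the end-to-end virtual spring.

    The bend angle relaxes exponentially (time constant ``tau_ns``) until
    the C6(res_a)-C6(res_b) chord reaches ``target_A``.
    """

    res_a: int = 2
    res_b: int = 29
    target_A: float = 12.0
    tau_ns: float = 10.0


@dataclass(frozen=True)
class IonSpec:
    species: str  # "MG" | "NA" | "CL"
    count: int
    bound_fraction: float = 0.0
    bind_distance: float = 3.3  # A
    mean_residence_ns: float = 20.0
    diffusion_step: float = 2.0  # A per frame for free ions
    bind_jitter: float = 0.05  # A, radial sd of the bound contact distance

    def __post_init__(self):
        if self.species not in ION_SPECIES:
            raise ValueError(f"unknown ion species {self.species!r}")
        if self.count < 0:
            raise ValueError("ion count must be >= 0")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0, 1]")
        if not self.bind_distance > 0:
            raise ValueError("bind_distance must be positive")


@dataclass(frozen=True)
class TrajectorySimSpec:
    build: DuplexBuildSpec = DuplexBuildSpec()
    n_frames: int = 2600
    dt_ns: float = 0.1
    sigma_per_residue: np.ndarray = field(default_factory=default_sigma_profile)
    open_prob_per_residue: np.ndarray = field(default_factory=default_open_prob_profile)
    open_displacement: float = 9.0  # A of extra separation across an open pair
    mean_open_dwell_ns: float = 2.0  # telegraph open-state mean dwell
    spring_pair: SpringSpec | None = None
    ions: tuple[IonSpec, ...] = ()
    box: tuple[float, float, float] = DEFAULT_BOX
    seed: int = 0

    def __post_init__(self):
        sig = np.asarray(self.sigma_per_residue, dtype=float)
        pop = np.asarray(self.open_prob_per_residue, dtype=float)
        if sig.shape != (DUPLEX_LENGTH,) or pop.shape != (DUPLEX_LENGTH,):
            raise ValueError(f"per-pair profiles must have length {DUPLEX_LENGTH}")
        if np.any(sig < 0):
            raise ValueError("sigma values must be >= 0")
        if np.any((pop < 0) | (pop > 1)):
            raise ValueError("open probabilities must be in [0, 1]")
        object.__setattr__(self, "sigma_per_residue", sig)
        object.__setattr__(self, "open_prob_per_residue", pop)
        object.__setattr__(self, "ions", tuple(self.ions))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.dt_ns > 0:
            raise ValueError("dt_ns must be positive")


@dataclass(frozen=True)
class IonGroundTruth:
    serial: int
    species: str
    host_p_serial: int | None  # phosphate the ion started bound to, if any
    bind_distance: float
    bound_intervals_ns: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class GroundTruth:
    sigma_per_pair: np.ndarray
    open_prob: np.ndarray
    realized_open_fraction: np.ndarray
    open_states: np.ndarray  # (n_frames, 30) bool
    bend_angle_deg: np.ndarray  # per frame
    spring: SpringSpec | None
    ions: tuple[IonGroundTruth, ...]
    seed: int


def _telegraph(rng, p: float, n_frames: int, dwell_open: float) -> np.ndarray:
    """Two-state telegraph sample with stationary open probability ``p``."""
    if p <= 0:
        return np.zeros(n_frames, dtype=bool)
    if p >= 1:
        return np.ones(n_frames, dtype=bool)
    q_open_to_closed = min(1.0 / dwell_open, 1.0)
    q_closed_to_open = min(q_open_to_closed * p / (1.0 - p), 1.0)
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    s = u[0] < p
    states[0] = s
    for t in range(1, n_frames):
        q = q_open_to_closed if s else q_closed_to_open
        if u[t] < q:
            s = not s
        states[t] = s
    return states


def _chord_function(build: DuplexBuildSpec, res_a: int, res_b: int):
    """C6(res_a)-C6(res_b) chord length as a function of bend angle (deg)."""
    ref_a = ideal_base_pair(build_pair_wc(build.sequence_b, res_a))
    ref_b = ideal_base_pair(build_pair_wc(build.sequence_b, res_b))
    c6_a = ref_a.atom_b("C6")
    c6_b = ref_b.atom_b("C6")

    def chord(theta_deg: float) -> float:
        origins, rots = pair_frames(
            DUPLEX_LENGTH, theta_deg, build.rise_per_bp, build.twist_per_bp
        )
        pa = origins[res_a - 1] + rots[res_a - 1] @ c6_a
        pb = origins[res_b - 1] + rots[res_b - 1] @ c6_b
        return float(np.linalg.norm(pa - pb))

    return chord


def build_pair_wc(sequence_b: str, res: int) -> str:
    from .core import COMPLEMENT

    b = sequence_b[res - 1]
    return b + COMPLEMENT[b]


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold coordinates into [0, length] with mirror reflection at the walls."""
    period = 2.0 * length
    y = np.mod(x, period)
    return length - np.abs(y - length)


def simulate_trajectory(spec: TrajectorySimSpec) -> tuple[Trajectory, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    topo_dna, base_frame = build_bent_duplex(spec.build)
    n_dna = topo_dna.n_atoms
    F = spec.n_frames
    box = np.asarray(spec.box, dtype=float)

    # centre the DNA in the box
    shift = box / 2 - base_frame.mean(axis=0)
    base_frame = base_frame + shift

    # --- bend-angle trajectory (spring emulation) -------------------------
    theta0 = spec.build.bend_angle_deg
    if spec.spring_pair is not None:
        sp = spec.spring_pair
        chord = _chord_function(spec.build, sp.res_a, sp.res_b)
        lo, hi = 1.0, 359.0
        if not (chord(hi) <= sp.target_A <= chord(lo)):
            raise ValueError(
                f"spring target {sp.target_A} A outside achievable chord range "
                f"[{chord(hi):.1f}, {chord(lo):.1f}]"
            )
        theta_target = brentq(lambda th: chord(th) - sp.target_A, lo, hi, xtol=1e-6)
        t_ns = np.arange(F) * spec.dt_ns
        theta_t = theta_target + (theta0 - theta_target) * np.exp(-t_ns / sp.tau_ns)
    else:
        theta_t = np.full(F, theta0)

    # --- mean structure per frame ----------------------------------------
    res_atoms = [topo_dna.residue_indices(r) for r in range(1, 2 * DUPLEX_LENGTH + 1)]
    coords = np.empty((F, n_dna, 3))
    if spec.spring_pair is None:
        coords[:] = base_frame
    else:
        # rebuild the duplex at each frame's bend angle (geometry only)
        local = {}
        for p in topo_dna.pairs:
            ref = ideal_base_pair(p.wc_type)
            local[p.res_b] = ref.coords_b
            local[p.res_c] = ref.coords_c
        strip_b = topo_dna.name[res_atoms[0]]
        for f in range(F):
            origins, rots = pair_frames(
                DUPLEX_LENGTH, theta_t[f], spec.build.rise_per_bp, spec.build.twist_per_bp
            )
            for p in topo_dna.pairs:
                i = p.res_b - 1
                for res_id, loc in ((p.res_b, local[p.res_b]), (p.res_c, local[p.res_c])):
                    idx = res_atoms[res_id - 1]
                    pts = loc @ rots[i].T + origins[i]
                    if len(idx) != len(pts):  # 5'-terminal residue without phosphate
                        pts = pts[-len(idx):]
                    coords[f, idx] = pts + shift

    # --- telegraph base-pair opening --------------------------------------
    dwell_frames = max(spec.mean_open_dwell_ns / spec.dt_ns, 1.0)
    open_states = np.zeros((F, DUPLEX_LENGTH), dtype=bool)
    for i in range(DUPLEX_LENGTH):
        open_states[:, i] = _telegraph(
            rng, float(spec.open_prob_per_residue[i]), F, dwell_frames
        )

    c6_b_idx = np.array([topo_dna.atom_index(p.res_b, "C6") for p in topo_dna.pairs])
    c6_c_idx = np.array([topo_dna.atom_index(p.res_c, "C6") for p in topo_dna.pairs])
    for i, p in enumerate(topo_dna.pairs):
        frames = np.flatnonzero(open_states[:, i])
        if frames.size:
            u = coords[frames, c6_c_idx[i]] - coords[frames, c6_b_idx[i]]
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            half = 0.5 * spec.open_displacement
            coords[np.ix_(frames, res_atoms[p.res_b - 1])] -= half * u[:, None, :]
            coords[np.ix_(frames, res_atoms[p.res_c - 1])] += half * u[:, None, :]

    # --- per-residue rigid Gaussian fluctuation ----------------------------
    # each residue is displaced independently (its pair's sigma applies to
    # both partners), so every atom fluctuates isotropically with std sigma
    for i, p in enumerate(topo_dna.pairs):
        s = float(spec.sigma_per_residue[i])
        if s > 0:
            for res_id in (p.res_b, p.res_c):
                disp = rng.normal(0.0, s, size=(F, 3))
                coords[:, res_atoms[res_id - 1]] += disp[:, None, :]

    # --- ions --------------------------------------------------------------
    p_atoms = np.flatnonzero((topo_dna.name == "P") & topo_dna.dna_mask)
    ion_coords = []
    ion_meta = []  # (species, ground truth record fields)
    serial_next = int(topo_dna.serial[-1]) + 1
    total_ns = F * spec.dt_ns
    for ion_spec in spec.ions:
        n_bound = int(round(ion_spec.bound_fraction * ion_spec.count))
        for k in range(ion_spec.count):
            pos = np.empty((F, 3))
            if k < n_bound and p_atoms.size:
                host = int(rng.integers(p_atoms.size))
                host_idx = p_atoms[host]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dur_ns = rng.exponential(ion_spec.mean_residence_ns)
                n_bound_frames = min(int(np.ceil(dur_ns / spec.dt_ns)), F)
                n_bound_frames = max(n_bound_frames, 1)
                radii = ion_spec.bind_distance + rng.normal(
                    0.0, ion_spec.bind_jitter, size=n_bound_frames
                )
                pos[:n_bound_frames] = (
                    coords[:n_bound_frames, host_idx]
                    + direction * radii[:, None]
                )
                if n_bound_frames < F:
                    n_free = F - n_bound_frames
                    steps = rng.normal(0.0, ion_spec.diffusion_step, size=(n_free, 3))
                    walk = pos[n_bound_frames - 1] + np.cumsum(steps, axis=0)
                    pos[n_bound_frames:] = np.column_stack(
                        [_reflect(walk[:, d], box[d]) for d in range(3)]
                    )
                intervals = ((0.0, n_bound_frames * spec.dt_ns),)
                host_serial = int(topo_dna.serial[host_idx])
            else:
                start = rng.random(3) * box
                steps = rng.normal(0.0, ion_spec.diffusion_step, size=(F, 3))
                steps[0] = 0.0
                walk = start + np.cumsum(steps, axis=0)
                pos = np.column_stack([_reflect(walk[:, d], box[d]) for d in range(3)])
                intervals = ()
                host_serial = None
            ion_coords.append(pos)
            ion_meta.append(
                IonGroundTruth(
                    serial_next,
                    ion_spec.species,
                    host_serial,
                    ion_spec.bind_distance,
                    intervals,
                )
            )
            serial_next += 1

    # --- assemble topology + trajectory ------------------------------------
    if ion_meta:
        n_ions = len(ion_meta)
        topo = Topology(
            serial=np.concatenate([topo_dna.serial, np.arange(n_dna + 1, n_dna + n_ions + 1)]),
            name=np.concatenate([topo_dna.name, [m.species for m in ion_meta]]),
            element=np.concatenate(
                [topo_dna.element, [infer_element(m.species, m.species) for m in ion_meta]]
            ),
            res_name=np.concatenate([topo_dna.res_name, [m.species for m in ion_meta]]),
            res_id=np.concatenate(
                [topo_dna.res_id, np.arange(61, 61 + n_ions)]
            ),
            chain_id=np.concatenate([topo_dna.chain_id, ["I"] * n_ions]),
            sequence_b=topo_dna.sequence_b,
            pairs=topo_dna.pairs,
        )
        all_coords = np.concatenate(
            [coords, np.stack(ion_coords, axis=1)], axis=1
        )
    else:
        topo = topo_dna
        all_coords = coords

    traj = Trajectory(topo, all_coords, spec.dt_ns, box=box)
    truth = GroundTruth(
        sigma_per_pair=spec.sigma_per_residue.copy(),
        open_prob=spec.open_prob_per_residue.copy(),
        realized_open_fraction=open_states.mean(axis=0),
        open_states=open_states,
        bend_angle_deg=theta_t,
        spring=spec.spring_pair,
        ions=tuple(ion_meta),
        seed=spec.seed,
    )
    return traj, truth


# --------------------------------------------------------------------------
# experimental-style curve generators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltingSimSpec:
    """Sigmoidal absorbance-vs-temperature curve with a known melting centre.

    Defaults mirror the measurement protocol: 20..80 C grid at 0.5 C steps.
    noise_sd is absolute absorbance noise (1% of the amplitude by default).
    """

    tm_true: float = 36.0
    width: float = 2.0  # C, logistic width
    a_low: float = 0.5
    a_high: float = 1.0
    t_start: float = 20.0
    t_stop: float = 80.0
    t_step: float = 0.5
    noise_sd: float = 0.005
    seed: int = 0
    label: str | float = ""

    def __post_init__(self):
        if not self.a_high > self.a_low:
            raise ValueError("a_high must exceed a_low")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not self.t_step > 0 or not self.t_stop > self.t_start:
            raise ValueError("temperature grid must be increasing")


def simulate_melting_curve(spec: MeltingSimSpec) -> MeltingCurve:
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.t_start, spec.t_stop + spec.t_step / 2, spec.t_step)
    amp = spec.a_high - spec.a_low
    logistic = 1.0 / (1.0 + np.exp(-(t - spec.tm_true) / spec.width))
    a = spec.a_low + amp * logistic
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, size=t.size)
    return MeltingCurve(t, a, spec.label)


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Two-peak donor/acceptor emission spectrum with a known proximity ratio.

    Peak (not integrated) intensities satisfy F_A/(F_A+F_D) = epr_true
    before noise; peaks sit at the donor/acceptor read-out wavelengths
    (570 / 670 nm) and are well separated at the default width.
    """

    epr_true: float = 0.4
    donor_center: float = DONOR_NM
    acceptor_center: float = ACCEPTOR_NM
    peak_width: float = 18.0  # nm, Gaussian sigma
    total_intensity: float = 1000.0
    noise_sd: float = 0.0
    wl_start: float = 500.0
    wl_stop: float = 750.0
    wl_step: float = 1.0
    seed: int = 0
    label: str | float = ""
    construct: str = "PI"

    def __post_init__(self):
        if not 0 <= self.epr_true <= 1:
            raise ValueError("epr_true must be in [0, 1]")


def simulate_spectrum(spec: SpectrumSimSpec) -> EmissionSpectrum:
    rng = np.random.default_rng(spec.seed)
    wl = np.arange(spec.wl_start, spec.wl_stop + spec.wl_step / 2, spec.wl_step)
    f_a = spec.total_intensity * spec.epr_true
    f_d = spec.total_intensity * (1.0 - spec.epr_true)
    g = lambda c: np.exp(-0.5 * ((wl - c) / spec.peak_width) ** 2)
    inten = f_d * g(spec.donor_center) + f_a * g(spec.acceptor_center)
    if spec.noise_sd > 0:
        inten = np.clip(inten + rng.normal(0.0, spec.noise_sd, size=wl.size), 0.0, None)
    return EmissionSpectrum(wl, inten, spec.label, spec.construct)
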