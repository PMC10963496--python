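"""Synthetic virtual subjects emulating a paired baseline/CTEPH study.

Real studies of chronic thromboembolic pulmonary hypertension (CTEPH) in
large animal models pair, per subject, a healthy baseline measurement set
with a diseased one after embolization: MPA systolic/diastolic pressure
and area, wedge pressure, and phase-contrast flow waveforms at the MPA,
LPA and RPA. This module generates the same measurement structure from a
known ground-truth model so that calibration and cohort statistics can be
validated end to end:

  * a bifurcating arterial tree with MPA/LPA/RPA roles and intralobar
    generations (canine-scale geometry by default);
  * a periodic inlet flow waveform (half-sine systolic ejection with an
    optional early-diastolic reverse notch, as seen in pulmonary MRI);
  * a diseased condition produced by parameter transforms rather than
    geometric clot insertion: distal resistance up (left-biased), outlet
    compliance down, wall stiffness up, stroke volume down;
  * radial velocity samples for the velocity-profile exponent fit.

Records are made *self-consistent* by fixed-point iteration: the model is
re-anchored to its own extracted measurements (stiffness estimate,
diastolic reference, nominal Windkessel set) until the extracted scalars
stabilize, so that the calibration pipeline applied to a noiseless record
reproduces the generating scaling factors exactly. Seeded Gaussian noise
is added last.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .calibration import SubjectRecord, nominal_from_record
from .network import ArterialNetwork, TimeSeries, Vessel
from .shear import RadialProfileSample, powerlaw_profile
from .solver import HemoState, SolverConfig, solve_to_periodic
from .wall import WallModel
from .windkessel import (
    ScalingFactors,
    WindkesselSet,
    apply_scaling,
    distribute_compliance,
    nominal_windkessels,
    total_compliance_from_decay,
)

__all__ = [
    "TreeSpec",
    "WaveformSpec",
    "CtephTransform",
    "VirtualSubject",
    "generate_tree",
    "generate_inlet_waveform",
    "make_virtual_subject",
    "sample_radial_profile",
    "default_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeSpec:
    """Geometry recipe for a synthetic bifurcating pulmonary tree.

    Defaults approximate a ~12 kg canine: MPA radius 0.7 cm, daughters
    shrinking by ~2^(-1/3) per generation (Murray-type branching), vessel
    length five times the inlet radius. ``radius_jitter`` and
    ``length_jitter`` perturb child radii and vessel lengths
    deterministically (seeded): real segmented networks are far from
    symmetric, and this anatomic spread is what produces low-flow,
    low-shear branches. Jitters are multiplicative, uniform in the log.
    """

    generations: int = 4
    root_radius: float = 0.7
    radius_ratio: float = 0.79
    length_to_radius: float = 5.0
    taper: float = 0.9  # outlet/inlet radius per vessel
    radius_jitter: float = 0.0
    length_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("need >= 2 generations (MPA, LPA, RPA)")
        if not 0.0 < self.radius_ratio <= 1.0:
            raise ValueError("radius_ratio must be in (0, 1]")


@dataclass(frozen=True)
class WaveformSpec:
    """Periodic inlet flow: half-sine systole, optional reverse notch.

    The net integral over one period equals ``stroke_volume`` (mL); with
    ``reverse_fraction`` f > 0, an early-diastolic half-sine notch carries
    a volume f * stroke_volume backwards (systole is scaled up by 1 + f to
    keep the net stroke volume). Defaults are canine-like: 0.5 s period
    (120 bpm), 40% systole, 20 mL stroke volume.
    """

    period: float = 0.5
    systolic_fraction: float = 0.4
    stroke_volume: float = 20.0
    reverse_fraction: float = 0.0
    notch_fraction: float = 0.15  # notch duration as a fraction of T
    n_samples: int = 128

    def __post_init__(self) -> None:
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic fraction must be in (0, 1)")
        if self.reverse_fraction < 0:
            raise ValueError("reverse fraction must be >= 0")


@dataclass(frozen=True)
class CtephTransform:
    """Parameter transform that turns the baseline truth into CTEPH.

    The obstruction raises outlet resistances everywhere with an extra
    left-lung bias (embolization concentrates in the left lung), lowers
    outlet compliance, stiffens the proximal wall, and lowers cardiac
    output — the haemodynamic signature of the disease without geometric
    clot insertion.
    """

    r_prox_mult: float = 2.0
    r_dist_mult: float = 4.1
    left_r_dist_extra: float = 1.25
    compliance_mult: float = 0.45
    stiffness_mult: float = 1.6
    stroke_factor: float = 0.67
    #: reverse-flow fraction of the diseased inlet waveform: hypertensive
    #: MPA flow develops notching with transient reversal from the strong
    #: wave reflections of the stiffened, obstructed bed
    reverse_fraction: float = 0.18


@dataclass
class VirtualSubject:
    """One paired virtual subject with ground truth retained.

    ``theta_truth`` is the scaling triple that maps the nominal
    Windkessel set (as the calibration pipeline derives it from the
    baseline record) onto the truth set — the exact recovery target for
    calibration on the noiseless baseline record. ``theta_truth_cteph``
    is the analogous (terminal-averaged) triple for the obstructed
    condition.
    """

    network: ArterialNetwork
    wall_truth: WallModel
    wall_truth_cteph: WallModel
    wk_truth_baseline: WindkesselSet
    wk_truth_cteph: WindkesselSet
    theta_truth: ScalingFactors
    theta_truth_cteph: ScalingFactors
    baseline_record: SubjectRecord
    cteph_record: SubjectRecord
    baseline_state: HemoState
    cteph_state: HemoState
    transform: CtephTransform
    noise: float
    seed: int
    waveform_baseline: TimeSeries = None
    waveform_cteph: TimeSeries = None


def generate_tree(spec: TreeSpec) -> ArterialNetwork:
    """Deterministic binary tree with 2^generations - 1 vessels."""
    rng = np.random.default_rng(spec.seed)
    vessels: dict[str, Vessel] = {}

    def add(vid, name, role, r_in, parent, depth):
        ljit = math.exp(spec.length_jitter * rng.uniform(-1.0, 1.0))
        length = spec.length_to_radius * r_in * ljit
        children = ()
        if depth < spec.generations - 1:
            children = (f"{vid}L", f"{vid}R")
        vessels[vid] = Vessel(
            id=vid,
            name=name,
            role=role,
            length=length,
            inlet_radius=r_in,
            outlet_radius=spec.taper * r_in,
            parent=parent,
            children=children,
        )
        for child in children:
            jit = 1.0 + spec.radius_jitter * rng.uniform(-1.0, 1.0)
            child_role = "intralobar" if depth >= 1 else (
                "LPA" if child.endswith("L") else "RPA"
            )
            add(
                child,
                child_role,
                child_role if depth == 0 else "intralobar",
                spec.taper * r_in * spec.radius_ratio * jit,
                vid,
                depth + 1,
            )

    add("MPA", "MPA", "MPA", spec.root_radius, None, 0)
    return ArterialNetwork(vessels=vessels)


def generate_inlet_waveform(spec: WaveformSpec) -> TimeSeries:
    """Periodic inlet flow waveform (mL/s) for one cardiac cycle."""
    t = np.linspace(0.0, spec.period, spec.n_samples, endpoint=False)
    t_sys = spec.systolic_fraction * spec.period
    sv_fwd = spec.stroke_volume * (1.0 + spec.reverse_fraction)
    q_peak = sv_fwd * math.pi / (2.0 * t_sys)
    q = np.where(t < t_sys, q_peak * np.sin(np.pi * t / t_sys), 0.0)
    if spec.reverse_fraction > 0:
        t_notch = spec.notch_fraction * spec.period
        sv_rev = spec.reverse_fraction * spec.stroke_volume
        q_notch = sv_rev * math.pi / (2.0 * t_notch)
        in_notch = (t >= t_sys) & (t < t_sys + t_notch)
        q = q - np.where(
            in_notch, q_notch * np.sin(np.pi * (t - t_sys) / t_notch), 0.0
        )
    return TimeSeries(times=t, values=q, period=spec.period)


def sample_radial_profile(
    gamma_true: float,
    u_mean: float,
    lumen_radius: float,
    n_radii: int = 12,
    n_sectors: int = 8,
    noise: float = 0.0,
    seed: int = 0,
) -> RadialProfileSample:
    """Sector-averaged radial velocity samples from a power-law profile.

    Each of ``n_sectors`` angular sectors observes the profile plus
    seeded Gaussian noise (std = noise * centerline velocity); the
    reported velocities are the sector averages, emulating intensity
    averaging of a 2D phase-contrast image. The wall sample carries noise
    only (no slip).
    """
    if n_radii < 4:
        raise ValueError("need at least 4 radial samples")
    rng = np.random.default_rng(seed)
    radii = np.linspace(0.0, lumen_radius, n_radii)
    u_true = powerlaw_profile(u_mean, lumen_radius, gamma_true, radii)
    u_center = u_mean * (gamma_true + 2.0) / gamma_true
    sectors = u_true[None, :] + rng.normal(
        0.0, noise * abs(u_center) if noise > 0 else 0.0,
        size=(n_sectors, n_radii),
    )
    return RadialProfileSample(
        radii=radii,
        velocities=sectors.mean(axis=0),
        lumen_radius=lumen_radius,
        n_sectors=n_sectors,
    )


# ---------------------------------------------------------------------------
# virtual-subject construction


def _extract_record(
    net: ArterialNetwork,
    state: HemoState,
    q_inlet: TimeSeries,
    p_pcw: float,
    t_decay: float,
    condition: str,
    n_samples: int = 32,
) -> SubjectRecord:
    """Measurement emulation: scalars at the MPA midplane, branch flows
    at the LPA/RPA midplanes resampled to the imaging frame count.

    Systolic values are cycle maxima; diastolic values are end-diastolic
    (cycle start, i.e. onset of ejection), which is robust to the early-
    diastolic pressure dip caused by the reverse-flow notch. Branch flows
    are sampled at the LPA/RPA inlet planes (just distal to the
    bifurcation, as phase-contrast planes are placed)."""
    root = net.root.id
    p = state.series(root, "pressure", 0.5)
    a = state.series(root, "area", 0.5)
    d1, d2 = net.root.children
    lpa = d1 if net.vessels[d1].role == "LPA" else d2
    rpa = d2 if lpa == d1 else d1
    t_frames = np.linspace(0.0, state.period, n_samples, endpoint=False)

    def resample(vid):
        vals = np.interp(t_frames, state.t, state.series(vid, "flow", 0.0))
        return TimeSeries(
            times=t_frames.copy(), values=vals, period=state.period
        )

    q_mpa = TimeSeries(
        times=t_frames.copy(),
        values=np.asarray(q_inlet(t_frames), dtype=float),
        period=state.period,
    )
    return SubjectRecord(
        p_sys=float(p.max()),
        p_dia=float(p[0]),
        p_pcw=p_pcw,
        a_sys=float(a.max()),
        a_dia=float(a[0]),
        q_mpa=q_mpa,
        q_lpa=resample(lpa),
        q_rpa=resample(rpa),
        condition=condition,
        t_decay=t_decay,
    )


def _anchor_truth_model(
    net: ArterialNetwork,
    wall_design: WallModel,
    wks_truth: WindkesselSet,
    q_inlet: TimeSeries,
    p_pcw: float,
    t_decay: float,
    condition: str,
    cfg: SolverConfig,
    n_samples: int,
    max_iter: int = 30,
    rtol: float = 5.0e-6,
) -> tuple[
    SubjectRecord, ArterialNetwork, WallModel, WindkesselSet, HemoState
]:
    """Anchor the truth model's diastolic reference to its own output.

    The designed Windkessel resistances and the designed stiffness K stay
    fixed (they carry the intended physiology); the tube-law reference is
    iterated: the MPA reference area is rescaled to the extracted
    diastolic area and the reference pressure is moved to the extracted
    diastolic pressure, until both stabilize. At the fixed point the
    record's analytic stiffness estimate returns exactly the designed K
    (because A_dia,measured == A0 at the measurement plane), so the
    calibration pipeline reconstructs this very model from the record.

    """
    from .calibration import _clone_network

    model_net = _clone_network(net)
    wall = wall_design
    wks = wks_truth
    state = solve_to_periodic(model_net, wall, wks, q_inlet, cfg)
    init = None
    for it in range(max_iter):
        record = _extract_record(
            model_net, state, q_inlet, p_pcw, t_decay, condition, n_samples
        )
        drift = max(
            abs(record.a_dia - wall.area_dia) / wall.area_dia,
            abs(record.p_dia - wall.pressure_dia)
            / max(abs(wall.pressure_dia), 1.0),
        )
        log.debug("anchor iter %d: drift %.2e", it, drift)
        if drift < rtol:
            break
        model_net = _clone_network(net)
        mpa = model_net.root
        a_mid = float(mpa.area_dia(0.5 * mpa.length))
        model_net.scale_areas(record.a_dia / a_mid, roles=("MPA",))
        wall = WallModel(
            stiffness=wall_design.stiffness,
            area_dia=record.a_dia,
            pressure_dia=record.p_dia,
        )
        vid0 = state.vessel_ids
        init = (
            np.concatenate([state.area[v][-1] for v in vid0]),
            np.concatenate([state.flow[v][-1] for v in vid0]),
        )
        state = solve_to_periodic(
            model_net, wall, wks, q_inlet, cfg, initial_state=init
        )
    record = _extract_record(
        model_net, state, q_inlet, p_pcw, t_decay, condition, n_samples
    )
    return record, model_net, wall, wks, state


def _implied_theta(
    wks_truth: WindkesselSet, wks_nominal: WindkesselSet
) -> ScalingFactors:
    """Global scaling triple mapping the record-derived nominal set onto
    the truth set (terminal-averaged; exact for unobstructed records)."""
    rp, rd, cc = [], [], []
    for tid, w in wks_truth.elements.items():
        wn = wks_nominal.elements[tid]
        rp.append(w.r_prox / wn.r_prox)
        rd.append(w.r_dist / wn.r_dist)
        cc.append(w.compliance / wn.compliance)
    return ScalingFactors(
        float(np.mean(rp)), float(np.mean(rd)), float(np.mean(cc))
    )


def _add_noise(
    record: SubjectRecord, noise: float, rng: np.random.Generator
) -> SubjectRecord:
    if noise <= 0:
        return record

    def noisy_series(ts: TimeSeries) -> TimeSeries:
        scale = noise * float(np.max(np.abs(ts.values)))
        return TimeSeries(
            times=ts.times.copy(),
            values=ts.values + rng.normal(0.0, scale, size=ts.values.shape),
            period=ts.period,
        )

    return SubjectRecord(
        p_sys=record.p_sys * (1.0 + noise * rng.standard_normal()),
        p_dia=record.p_dia * (1.0 + noise * rng.standard_normal()),
        p_pcw=record.p_pcw,
        a_sys=record.a_sys * (1.0 + noise * rng.standard_normal()),
        a_dia=record.a_dia * (1.0 + noise * rng.standard_normal()),
        q_mpa=noisy_series(record.q_mpa),
        q_lpa=noisy_series(record.q_lpa),
        q_rpa=noisy_series(record.q_rpa),
        condition=record.condition,
        t_decay=record.t_decay,
    )


def make_virtual_subject(
    tree_spec: TreeSpec = TreeSpec(),
    waveform_spec: WaveformSpec = WaveformSpec(reverse_fraction=0.05),
    stiffness: float = 40.0,
    p_dia_init: float = 12.0,
    p_sys_init: float = 20.0,
    p_pcw: float = 5.0,
    theta_truth: ScalingFactors = ScalingFactors(1.0, 1.0, 1.0),
    transform: CtephTransform = CtephTransform(),
    bed_jitter: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    solver_config: SolverConfig = SolverConfig(dx=0.25, dt=2.0e-4,
                                               cycle_tolerance=1e-8),
    n_samples: int = 32,
) -> VirtualSubject:
    """Generate one paired baseline/CTEPH virtual subject.

    The baseline truth model is designed from physiologic targets
    (sys/dia pressures, wedge pressure, stiffness Eh/r0 in mmHg): outlet
    resistances from the target mean pressure and the Poiseuille flow
    split, total compliance from the target diastolic decay, optionally
    scaled by ``theta_truth``. The truth Windkessels then stay *fixed*
    while the tube-law diastolic reference is anchored to the model's own
    output, so the record is exactly self-consistent with the calibration
    pipeline's model reconstruction. The CTEPH condition applies
    :class:`CtephTransform` to the baseline truth and repeats the
    anchoring. ``VirtualSubject.theta_truth`` reports the implied global
    scaling triple (truth set over record-derived nominal set) that
    calibration should recover. Noise is seeded and applied last.
    """
    rng = np.random.default_rng(seed)
    net = generate_tree(tree_spec)
    # the truth model is driven by the waveform exactly as the record will
    # carry it (imaging frame count), so the record is fully consistent
    # with the inlet condition the calibration pipeline prescribes
    q_base = generate_inlet_waveform(
        replace(waveform_spec, n_samples=n_samples)
    )
    t_decay = (1.0 - waveform_spec.systolic_fraction) * waveform_spec.period

    # --- baseline truth from design targets ------------------------------
    mpa = net.root
    a_dia0 = float(mpa.area_dia(0.5 * mpa.length))
    wall0 = WallModel(
        stiffness=stiffness, area_dia=a_dia0, pressure_dia=p_dia_init
    )
    mpap0 = p_sys_init / 3.0 + 2.0 * p_dia_init / 3.0
    wks0 = nominal_windkessels(net, mpap0, p_pcw, q_base.mean)
    # design compliance from the diastolic decay with the R_D-based time
    # constant: in a WK3 the capacitor discharges through the distal
    # resistance, so tau = R_D_total * C_total governs the pressure fall
    c0 = total_compliance_from_decay(
        p_sys_init, p_dia_init, p_pcw, t_decay, wks0.r_dist_total
    )
    wks0 = distribute_compliance(c0, wks0)
    if bed_jitter > 0:
        # downstream-bed heterogeneity: each terminal's true resistance
        # deviates lognormally from the size-based (Poiseuille) nominal,
        # the way real vascular beds do; compliance follows conductance
        rng_bed = np.random.default_rng(seed + 1)
        r_total_design = wks0.r_total
        elements = {}
        for tid, w in wks0.elements.items():
            f = float(np.exp(bed_jitter * rng_bed.standard_normal()))
            elements[tid] = replace(
                w, r_prox=w.r_prox * f, r_dist=w.r_dist * f
            )
        jittered = WindkesselSet(elements)
        # renormalize so the network total resistance (and hence the
        # design mean pressure) is unchanged by the heterogeneity
        norm = r_total_design / jittered.r_total
        elements = {
            tid: replace(w, r_prox=w.r_prox * norm, r_dist=w.r_dist * norm)
            for tid, w in jittered.elements.items()
        }
        wks0 = distribute_compliance(c0, WindkesselSet(elements))
    base_wks = apply_scaling(wks0, theta_truth)

    (
        base_record, base_net, base_wall, base_wks, base_state
    ) = _anchor_truth_model(
        net, wall0, base_wks, q_base, p_pcw, t_decay,
        "baseline", solver_config, n_samples,
    )
    theta_base = _implied_theta(
        base_wks, nominal_from_record(base_net, base_record)
    )

    # --- CTEPH truth: transform the baseline truth, then re-anchor -------
    q_cteph = generate_inlet_waveform(
        replace(
            waveform_spec,
            n_samples=n_samples,
            stroke_volume=waveform_spec.stroke_volume
            * transform.stroke_factor,
            reverse_fraction=max(
                transform.reverse_fraction, waveform_spec.reverse_fraction
            ),
        )
    )
    lpa = next(v.id for v in net.vessels.values() if v.role == "LPA")
    left_terms = set(net.downstream_terminals(lpa))
    elements = {}
    for tid, w in base_wks.elements.items():
        extra = transform.left_r_dist_extra if tid in left_terms else 1.0
        elements[tid] = replace(
            w,
            r_prox=w.r_prox * transform.r_prox_mult,
            r_dist=w.r_dist * transform.r_dist_mult * extra,
            compliance=w.compliance * transform.compliance_mult,
        )
    wks_cteph = WindkesselSet(elements)
    wall_cteph0 = WallModel(
        stiffness=base_wall.stiffness * transform.stiffness_mult,
        area_dia=base_wall.area_dia,
        pressure_dia=base_wall.pressure_dia,
    )

    (
        cteph_record, cteph_net, cteph_wall, wks_cteph, cteph_state
    ) = _anchor_truth_model(
        net, wall_cteph0, wks_cteph, q_cteph, p_pcw, t_decay,
        "CTEPH", solver_config, n_samples,
    )
    theta_cteph = _implied_theta(
        wks_cteph, nominal_from_record(cteph_net, cteph_record)
    )

    return VirtualSubject(
        network=net,
        wall_truth=base_wall,
        wall_truth_cteph=cteph_wall,
        wk_truth_baseline=base_wks,
        wk_truth_cteph=wks_cteph,
        theta_truth=theta_base,
        theta_truth_cteph=theta_cteph,
        baseline_record=_add_noise(base_record, noise, rng),
        cteph_record=_add_noise(cteph_record, noise, rng),
        baseline_state=base_state,
        cteph_state=cteph_state,
        transform=transform,
        noise=noise,
        seed=seed,
        waveform_baseline=q_base,
        waveform_cteph=q_cteph,
    )


def default_cohort(
    n_subjects: int = 5,
    seed: int = 0,
    noise: float = 0.0,
    solver_config: SolverConfig = SolverConfig(dx=0.25, dt=2.0e-4,
                                               cycle_tolerance=1e-8),
) -> list[VirtualSubject]:
    """A paired cohort with deterministic between-subject variability.

    Subject-to-subject variation draws (seeded) the tree radius, stroke
    volume, period, stiffness, and the severity of the CTEPH transform
    from modest ranges around the defaults, emulating biological spread.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        tree = TreeSpec(
            root_radius=float(rng.uniform(0.62, 0.78)),
            radius_ratio=0.86,
            taper=0.93,
            radius_jitter=0.15,
            length_jitter=0.7,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        wf = WaveformSpec(
            period=float(rng.uniform(0.45, 0.55)),
            stroke_volume=float(rng.uniform(17.0, 23.0)),
            reverse_fraction=0.05,
        )
        tf = CtephTransform(
            r_prox_mult=float(rng.uniform(1.8, 2.2)),
            r_dist_mult=float(rng.uniform(3.8, 4.4)),
            left_r_dist_extra=float(rng.uniform(1.15, 1.35)),
            compliance_mult=float(rng.uniform(0.4, 0.55)),
            stiffness_mult=float(rng.uniform(1.4, 1.8)),
            stroke_factor=float(rng.uniform(0.62, 0.72)),
        )
        subjects.append(
            make_virtual_subject(
                tree_spec=tree,
                waveform_spec=wf,
                stiffness=float(rng.uniform(35.0, 45.0)),
                theta_truth=ScalingFactors(1.0, 1.0, 1.0),
                transform=tf,
                noise=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
                solver_config=solver_config,
            )
        )
    return subjects
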