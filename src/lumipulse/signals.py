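"""Parametric luciferase reporter time-courses and synthetic experiments.

Each :class:`SignalProfile` is a closed-form rate (Hz above the sensor dark
floor) as a function of time since session start:

* ``constant``    -- steady basal transactivation;
* ``rise_decay``  -- ligand-induced activation: latency, saturating rise,
  exponential decay, ``(1 - e^{-u/tau_r}) e^{-u/tau_d}`` scaled so the peak
  equals ``peak_rate`` (peak at ``u* = tau_r * ln(1 + tau_d/tau_r)``);
* ``depletion``   -- same shape from t=0, for bright reporters whose substrate
  depletes over the session;
* ``cosine``      -- circadian oscillation ``M + A e^{-lam t} cos(2pi(t-phi)/P)``
  clipped at zero, default period 30 h;
* ``growth_ramp`` -- exponential proliferation, ``initial * 2^{t/Td}``.

Treatments modulate a profile multiplicatively: an ``inhibit`` effect applies
Hill scaling ``1 / (1 + (c/IC50)^n)`` from its time onward; an ``activate``
effect is a unit-scaling marker recording when a ligand was added (the shape
of the response lives in the profile's latency).

:func:`generate_experiment` drives the device model end to end, producing a
serial log plus a ground-truth table of per-window true rates, so that the
whole processing/analysis stack can be validated against known inputs.
Presets emulate six assay classes: growth-factor activation (FGF2, EGF),
kinase inhibition (ARQ087), Wnt pathway activation (CHIR99021), cytotoxicity
(vemurafenib), NF-kB induction (TNF-alpha), circadian BMAL1 oscillation, and
NanoLuc substrate depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .device import AcquisitionConfig, SensorSpec, mcu_acquire, simulate_pulse_train

__all__ = [
    "SignalProfile",
    "TreatmentEffect",
    "WellDesign",
    "ExperimentDesign",
    "hill_inhibition",
    "profile_rate",
    "rise_decay_peak_time",
    "apply_treatments",
    "generate_experiment",
    "preset_design",
    "PRESETS",
]

_VARIANT_PARAMS = {
    "constant": {"level"},
    "rise_decay": {"latency", "rise_tau", "peak_rate", "decay_tau"},
    "depletion": {"peak_rate", "rise_tau", "depletion_tau"},
    "cosine": {"mesor", "amplitude", "period", "acrophase", "damping"},
    "growth_ramp": {"initial", "doubling_time"},
}

#: Default circadian period in seconds (30 h).
DEFAULT_PERIOD_S = 30.0 * 3600.0

_COSINE_DEFAULTS = {"period": DEFAULT_PERIOD_S, "acrophase": 0.0, "damping": 0.0}


@dataclass(frozen=True)
class SignalProfile:
    """One parametric luminescence time-course (Hz above baseline)."""

    variant: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_PARAMS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{sorted(_VARIANT_PARAMS)}"
            )
        params = dict(self.params)
        if self.variant == "cosine":
            for k, v in _COSINE_DEFAULTS.items():
                params.setdefault(k, v)
        expected = _VARIANT_PARAMS[self.variant]
        missing = expected - params.keys()
        extra = params.keys() - expected
        if missing or extra:
            raise ValueError(
                f"variant {self.variant!r}: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for key in ("rise_tau", "decay_tau", "depletion_tau", "period", "doubling_time"):
            if key in params and params[key] <= 0:
                raise ValueError(f"{key} must be positive")
        for key in ("level", "peak_rate", "mesor", "amplitude", "initial"):
            if key in params and params[key] < 0:
                raise ValueError(f"{key} must be non-negative")
        if "damping" in params and params["damping"] < 0:
            raise ValueError("damping must be non-negative")
        object.__setattr__(self, "params", MappingProxyType(params))

    # -- convenient constructors ------------------------------------------
    @classmethod
    def constant(cls, level: float) -> "SignalProfile":
        return cls("constant", {"level": level})

    @classmethod
    def rise_decay(
        cls, latency: float, rise_tau: float, peak_rate: float, decay_tau: float
    ) -> "SignalProfile":
        return cls(
            "rise_decay",
            {
                "latency": latency,
                "rise_tau": rise_tau,
                "peak_rate": peak_rate,
                "decay_tau": decay_tau,
            },
        )

    @classmethod
    def depletion(
        cls, peak_rate: float, rise_tau: float, depletion_tau: float
    ) -> "SignalProfile":
        return cls(
            "depletion",
            {
                "peak_rate": peak_rate,
                "rise_tau": rise_tau,
                "depletion_tau": depletion_tau,
            },
        )

    @classmethod
    def cosine(
        cls,
        mesor: float,
        amplitude: float,
        period: float = DEFAULT_PERIOD_S,
        acrophase: float = 0.0,
        damping: float = 0.0,
    ) -> "SignalProfile":
        return cls(
            "cosine",
            {
                "mesor": mesor,
                "amplitude": amplitude,
                "period": period,
                "acrophase": acrophase,
                "damping": damping,
            },
        )

    @classmethod
    def growth_ramp(cls, initial: float, doubling_time: float) -> "SignalProfile":
        return cls("growth_ramp", {"initial": initial, "doubling_time": doubling_time})

    def rate(self, t) -> np.ndarray:
        return profile_rate(self, t)


def _rise_decay_shape(u: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unnormalised activation shape, zero for u < 0."""
    s = np.where(
        u >= 0,
        (1.0 - np.exp(-np.maximum(u, 0.0) / rise_tau))
        * np.exp(-np.maximum(u, 0.0) / decay_tau),
        0.0,
    )
    return s


def rise_decay_peak_time(profile: SignalProfile) -> float:
    """Time of the profile maximum: ``latency + tau_r * ln(1 + tau_d/tau_r)``."""
    p = profile.params
    if profile.variant == "rise_decay":
        return p["latency"] + p["rise_tau"] * math.log(1.0 + p["decay_tau"] / p["rise_tau"])
    if profile.variant == "depletion":
        return p["rise_tau"] * math.log(1.0 + p["depletion_tau"] / p["rise_tau"])
    raise ValueError("peak time is defined for rise_decay and depletion profiles")


def profile_rate(profile: SignalProfile, t) -> np.ndarray | float:
    """Evaluate the profile rate in Hz at time(s) ``t`` (seconds, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    p = profile.params
    v = profile.variant
    if v == "constant":
        out = np.full_like(t_arr, p["level"])
    elif v == "rise_decay":
        u = t_arr - p["latency"]
        peak = _rise_decay_shape(
            np.asarray(p["rise_tau"] * math.log(1.0 + p["decay_tau"] / p["rise_tau"])),
            p["rise_tau"],
            p["decay_tau"],
        )
        out = p["peak_rate"] * _rise_decay_shape(u, p["rise_tau"], p["decay_tau"]) / peak
    elif v == "depletion":
        peak = _rise_decay_shape(
            np.asarray(p["rise_tau"] * math.log(1.0 + p["depletion_tau"] / p["rise_tau"])),
            p["rise_tau"],
            p["depletion_tau"],
        )
        out = (
            p["peak_rate"]
            * _rise_decay_shape(t_arr, p["rise_tau"], p["depletion_tau"])
            / peak
        )
    elif v == "cosine":
        osc = p["amplitude"] * np.exp(-p["damping"] * t_arr) * np.cos(
            2.0 * math.pi * (t_arr - p["acrophase"]) / p["period"]
        )
        out = np.maximum(p["mesor"] + osc, 0.0)  # rate cannot go negative
    elif v == "growth_ramp":
        out = p["initial"] * np.power(2.0, t_arr / p["doubling_time"])
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown variant {v!r}")
    return float(out) if out.ndim == 0 else out


def hill_inhibition(concentration: float, ic50: float, hill_n: float = 1.0) -> float:
    """Fractional activity remaining under a competitive inhibitor.

    ``1 / (1 + (c/IC50)^n)``: 1 at zero dose, 0.5 at the IC50, -> 0 at
    saturating dose.
    """
    if concentration < 0 or ic50 <= 0 or hill_n <= 0:
        raise ValueError("require concentration >= 0, ic50 > 0, hill_n > 0")
    return 1.0 / (1.0 + (concentration / ic50) ** hill_n)


@dataclass(frozen=True)
class TreatmentEffect:
    """A treatment applied at a given session time.

    ``inhibit`` scales the profile by a Hill factor from ``time`` onward;
    ``activate`` has unit scaling and records when a stimulating ligand was
    added (for downstream kinetics summaries).
    """

    time: float
    kind: str
    concentration: float = 0.0
    ic50: float = 1.0
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("activate", "inhibit"):
            raise ValueError(f"kind must be 'activate' or 'inhibit', got {self.kind!r}")
        if self.time < 0:
            raise ValueError("treatment time must be >= 0")
        if self.kind == "inhibit":
            s = hill_inhibition(self.concentration, self.ic50, self.hill_n)
            if not 0.0 <= s <= 1.0:
                raise ValueError("inhibition scaling must lie in [0, 1]")

    @property
    def scaling(self) -> float:
        if self.kind == "activate":
            return 1.0
        return hill_inhibition(self.concentration, self.ic50, self.hill_n)


def apply_treatments(
    profile: SignalProfile, effects: Sequence[TreatmentEffect], t
) -> np.ndarray | float:
    """Profile rate with every active treatment's scaling applied.

    Effects must be sorted by time; each effect scales the rate for
    ``t >= effect.time`` and the scalings multiply.  Before the first effect
    time the profile is unchanged.
    """
    times = [e.time for e in effects]
    if times != sorted(times):
        raise ValueError("effects must be sorted by time")
    t_arr = np.asarray(t, dtype=float)
    rate = np.asarray(profile_rate(profile, t_arr), dtype=float)
    for e in effects:
        rate = np.where(t_arr >= e.time, rate * e.scaling, rate)
    return float(rate) if rate.ndim == 0 else rate


@dataclass(frozen=True)
class WellDesign:
    """One well: its signal profile, treatments, and replicate grouping.

    ``basal_rate`` is a constant reporter rate (Hz) present throughout the
    session on top of the profile, emulating basal transactivation after
    luciferin addition.
    """

    well_id: str
    profile: SignalProfile
    treatments: tuple[TreatmentEffect, ...] = ()
    replicate_group: str = "default"
    basal_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if self.basal_rate < 0:
            raise ValueError("basal_rate must be >= 0")

    def rate(self, t) -> np.ndarray | float:
        base = apply_treatments(self.profile, self.treatments, t)
        return np.asarray(base) + self.basal_rate


@dataclass(frozen=True)
class ExperimentDesign:
    """A full synthetic session: wells + acquisition settings + sensor."""

    wells: tuple[WellDesign, ...]
    acquisition: AcquisitionConfig
    sensor: SensorSpec = SensorSpec()

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if len(self.wells) != self.acquisition.n_wells:
            raise ValueError(
                f"design has {len(self.wells)} wells but acquisition declares "
                f"{self.acquisition.n_wells}"
            )
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_id labels must be unique")
        groups = [w.replicate_group for w in self.wells]
        if any(not g for g in groups):
            raise ValueError("replicate groups must be non-empty labels")


def _well_rng(master_seed: int, well_index: int) -> np.random.Generator:
    """Independent, reproducible stream per well from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(well_index,)))


def generate_experiment(
    design: ExperimentDesign, *, seed: int | None = None
) -> tuple[str, pd.DataFrame]:
    """Simulate the design end to end.

    Returns the serial log text (canonical dialect, parseable by
    :func:`lumipulse.logio.read_log`) and a ground-truth table with the true
    signal rate at each window midpoint and the expected total counts per
    window (``(f_D + rate) * T``), for recovery tests.

    Identical designs and seeds produce byte-identical logs.
    """
    from . import logio  # local import: logio depends on this module's types

    acq = design.acquisition
    master = acq.seed if seed is None else seed
    trains = []
    for i, well in enumerate(design.wells):
        trains.append(
            simulate_pulse_train(
                well.rate,
                design.sensor,
                acq,
                well.well_id,
                rng=_well_rng(master, i),
            )
        )
    series = mcu_acquire(trains, acq)
    header = logio.LogHeader(
        device_id="SIM",
        n_wells=acq.n_wells,
        integration_window_ms=int(round(acq.integration_window * 1000)),
        wells=tuple(w.well_id for w in design.wells),
        session_start="0",
    )
    log_text = logio.write_log(series, header)

    rows = []
    mids = np.arange(acq.n_windows) * acq.integration_window + acq.integration_window / 2
    for well in design.wells:
        rate = np.asarray(well.rate(mids), dtype=float)
        total = np.minimum(design.sensor.dark_frequency + rate, design.sensor.max_frequency)
        for k in range(acq.n_windows):
            rows.append(
                {
                    "well_id": well.well_id,
                    "replicate_group": well.replicate_group,
                    "window_index": k,
                    "time_s": mids[k],
                    "true_rate_hz": rate[k],
                    "expected_counts": total[k] * acq.integration_window,
                }
            )
    return log_text, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets emulating the six in-study assay classes
# ---------------------------------------------------------------------------

def _replicated(base_id, profile, treatments, group, basal, n):
    return [
        WellDesign(f"{base_id}{i + 1}", profile, treatments, group, basal)
        for i in range(n)
    ]


def _fgf2_design(seed: int) -> ExperimentDesign:
    # Growth-factor activation on a 5-min window: basal ~0.06 Hz total
    # (0.02 Hz floor + 0.04 Hz basal transactivation), FGF2 at 1 h, peak
    # ~0.47 Hz total (142 counts / 5 min) 5 h after treatment.
    treat = 3600.0
    profile = SignalProfile.rise_decay(
        latency=treat, rise_tau=9000.0, peak_rate=0.4133, decay_tau=57500.0
    )
    wells = _replicated("F", profile, (TreatmentEffect(treat, "activate"),), "fgf2", 0.04, 3)
    wells += _replicated("C", SignalProfile.constant(0.0), (), "control", 0.04, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=43200.0, integration_window=300.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _egf_design(seed: int) -> ExperimentDesign:
    treat = 1800.0
    profile = SignalProfile.rise_decay(
        latency=treat, rise_tau=9000.0, peak_rate=0.09, decay_tau=57500.0
    )
    wells = _replicated("E", profile, (TreatmentEffect(treat, "activate"),), "egf", 0.01, 3)
    wells += _replicated("C", SignalProfile.constant(0.0), (), "control", 0.01, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=43200.0, integration_window=600.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _arq087_design(seed: int) -> ExperimentDesign:
    # FGF2 activation under increasing doses of an FGFR kinase inhibitor
    # (pre-added 30 min before the ligand); Hill IC50 50 nM.
    profile = SignalProfile.rise_decay(
        latency=1800.0, rise_tau=9000.0, peak_rate=0.41, decay_tau=57500.0
    )
    doses_nm = [0.0, 50.0, 100.0, 250.0, 500.0, 1000.0]
    wells = []
    for i, c in enumerate(doses_nm):
        effects = [TreatmentEffect(0.0, "inhibit", concentration=c, ic50=50.0)] if c else []
        effects.append(TreatmentEffect(1800.0, "activate"))
        wells.append(
            WellDesign(f"D{i + 1}", profile, tuple(effects), f"arq087_{int(c)}nM", 0.04)
        )
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=43200.0, integration_window=300.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _wnt_design(seed: int) -> ExperimentDesign:
    # GSK3 inhibition on a 30-min window over ~1000 min: signal climbs to
    # ~26 counts/30 min at 600 min then declines; control creeps up slowly.
    profile = SignalProfile.rise_decay(
        latency=0.0, rise_tau=18000.0, peak_rate=26.0 / 1800.0, decay_tau=115000.0
    )
    wells = _replicated("W", profile, (TreatmentEffect(0.0, "activate"),), "chir99021", 0.0, 3)
    ctrl = SignalProfile.growth_ramp(initial=4.0 / 1800.0, doubling_time=102000.0)
    wells += _replicated("C", ctrl, (), "control", 0.0, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=60000.0, integration_window=1800.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _nfkb_design(seed: int) -> ExperimentDesign:
    # TNF-alpha induction on a 10-min window: rises through the session,
    # reaching ~46 counts/10 min by ~1000 min; untreated drifts 2 -> 7.
    profile = SignalProfile.rise_decay(
        latency=0.0, rise_tau=20000.0, peak_rate=0.0807, decay_tau=1e6
    )
    wells = _replicated("T", profile, (TreatmentEffect(0.0, "activate"),), "tnfa", 0.003, 3)
    ctrl = SignalProfile.growth_ramp(initial=1.5 / 600.0, doubling_time=28000.0)
    wells += _replicated("C", ctrl, (), "control", 0.0, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=60000.0, integration_window=600.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _vemurafenib_design(seed: int) -> ExperimentDesign:
    # Cytotoxicity on a 20-min window over 24 h: proliferating control grows
    # ~14 -> 87 counts/20 min; drug-arrested cells stay low (~16 counts).
    ctrl = SignalProfile.growth_ramp(initial=14.0 / 1200.0, doubling_time=32800.0)
    wells = _replicated("C", ctrl, (), "control", 0.0, 3)
    treated = SignalProfile.constant(16.0 / 1200.0)
    wells += _replicated("V", treated, (), "vemurafenib", 0.0, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=6, total_duration=86400.0, integration_window=1200.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _bmal1_design(seed: int) -> ExperimentDesign:
    # Circadian reporter after serum shock: 52-h session, 2-h windows,
    # 30-h period; mesor ~100 counts/2 h with ~60-count swing.
    profile = SignalProfile.cosine(
        mesor=100.0 / 7200.0,
        amplitude=60.0 / 7200.0,
        period=DEFAULT_PERIOD_S,
        acrophase=12.0 * 3600.0,
    )
    wells = _replicated("B", profile, (), "bmal1", 0.0, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=3, total_duration=52.0 * 3600.0, integration_window=7200.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


def _nanoluc_design(seed: int) -> ExperimentDesign:
    # Bright engineered luciferase with substrate depletion: fast onset,
    # peak ~170 counts/20 min around 5 h, gradual decline.
    profile = SignalProfile.depletion(
        peak_rate=170.0 / 1200.0, rise_tau=9000.0, depletion_tau=60000.0
    )
    wells = _replicated("N", profile, (), "nanoluc", 0.0, 3)
    return ExperimentDesign(
        wells=tuple(wells),
        acquisition=AcquisitionConfig(
            n_wells=3, total_duration=57600.0, integration_window=1200.0, seed=seed
        ),
        sensor=SensorSpec(dark_frequency=0.02),
    )


PRESETS = {
    "fgf2": _fgf2_design,
    "egf": _egf_design,
    "arq087": _arq087_design,
    "wnt": _wnt_design,
    "nfkb": _nfkb_design,
    "vemurafenib": _vemurafenib_design,
    "bmal1": _bmal1_design,
    "nanoluc": _nanoluc_design,
}


def preset_design(name: str, seed: int = 0) -> ExperimentDesign:
    """Build one of the bundled assay-class designs."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory(seed)
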