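"""Protocols, traces and feature extraction for whole-cell pump-current records.

An experiment is a timeline of external-solution epochs (Na, K, Ca,
blockers).  A :class:`Trace` is the sampled current-density record the
experiment produces, and :func:`extract_features` measures, per K-application
epoch, the quantities the analysis works with: peak current, plateau
current, fractional decay ``F_decay = 1 - I_plateau/I_peak``, a
single-exponential fit of the decay, and the initial fractional decay rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

__all__ = [
    "Epoch",
    "Protocol",
    "Trace",
    "EpochFeatures",
    "FeatureSet",
    "make_protocol",
    "extract_features",
    "apply_switch_filter",
]

_CONTIGUITY_TOL = 1e-9


@dataclass(frozen=True)
class Epoch:
    """One external-solution condition held for ``duration_s`` seconds.

    ``ca_episode`` marks a Ca-influx episode (reverse Na/Ca-exchange
    activation) whose after-effects the inactivation model's Ca modulation
    responds to.
    """

    label: str
    start_s: float
    duration_s: float
    K_mM: float = 0.0
    Na_mM: float = 0.0
    Ca_mM: float = 0.0
    ouabain: bool = False
    Ni: bool = False
    ca_episode: bool = False

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError(f"epoch {self.label!r}: duration must be > 0")
        if min(self.K_mM, self.Na_mM, self.Ca_mM) < 0:
            raise ValidationError(f"epoch {self.label!r}: concentrations must be >= 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def is_k_epoch(self) -> bool:
        """True when extracellular K is present and pumps are not blocked."""
        return self.K_mM > 0 and not self.ouabain


@dataclass(frozen=True)
class Protocol:
    """Ordered, contiguous, non-overlapping epochs plus the solution-switch
    time constant (metadata; generators may apply it as a first-order filter)."""

    epochs: tuple[Epoch, ...]
    switch_tau_s: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValidationError("protocol must contain at least one epoch")
        if self.switch_tau_s < 0:
            raise ValidationError("switch_tau_s must be >= 0")
        for prev, nxt in zip(self.epochs, self.epochs[1:]):
            if abs(nxt.start_s - prev.end_s) > _CONTIGUITY_TOL:
                raise ValidationError(
                    f"epochs {prev.label!r} and {nxt.label!r} are not contiguous "
                    f"(gap/overlap of {nxt.start_s - prev.end_s:g} s)"
                )
        n_ca = sum(e.ca_episode for e in self.epochs)
        if n_ca > 1:
            raise ValidationError("at most one Ca episode per protocol is supported")

    @property
    def start_s(self) -> float:
        return self.epochs[0].start_s

    @property
    def end_s(self) -> float:
        return self.epochs[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def k_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.is_k_epoch]

    def ca_episode(self) -> Epoch | None:
        for e in self.epochs:
            if e.ca_episode:
                return e
        return None

    def epoch_at(self, t: float) -> Epoch:
        for e in self.epochs:
            if e.start_s - _CONTIGUITY_TOL <= t < e.end_s:
                return e
        return self.epochs[-1]

    def to_dict(self) -> dict:
        return {
            "switch_tau_s": self.switch_tau_s,
            "epochs": [
                {
                    "label": e.label,
                    "start_s": e.start_s,
                    "duration_s": e.duration_s,
                    "K_mM": e.K_mM,
                    "Na_mM": e.Na_mM,
                    "Ca_mM": e.Ca_mM,
                    "ouabain": e.ouabain,
                    "Ni": e.Ni,
                    "ca_episode": e.ca_episode,
                }
                for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            epochs=tuple(Epoch(**e) for e in d["epochs"]),
            switch_tau_s=d.get("switch_tau_s", 0.1),
        )


@dataclass
class Trace:
    """Uniformly sampled current-density time series.

    current is in pA/pF (capacitance-normalized); the optional capacitance
    column is in pF.  ``extras`` holds additional synchronous channels
    (e.g. exchanger current or pool Na from the coupled simulation) that the
    CSV writer emits as extra columns.
    """

    time_s: np.ndarray
    i_pApF: np.ndarray
    cm_pF: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i_pApF = np.asarray(self.i_pApF, dtype=float)
        if self.time_s.shape != self.i_pApF.shape:
            raise ValidationError("time and current columns must have equal length")
        if self.cm_pF is not None:
            self.cm_pF = np.asarray(self.cm_pF, dtype=float)
            if self.cm_pF.shape != self.time_s.shape:
                raise ValidationError("capacitance column length mismatch")
        for k, v in self.extras.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != self.time_s.shape:
                raise ValidationError(f"extra column {k!r} length mismatch")
            self.extras[k] = arr
        if self.time_s.size >= 2:
            dts = np.diff(self.time_s)
            dt = dts[0]
            if dt <= 0 or np.any(np.abs(dts - dt) > 1e-6 * dt):
                raise ValidationError("time grid must be uniform with dt > 0")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if self.time_s.size >= 2 else math.nan

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= t < t1."""
        return (self.time_s >= t0 - 1e-12) & (self.time_s < t1 - 1e-12)


@dataclass
class ExpFit:
    """Single-exponential decay fit I(t) = Iinf + (I0 - Iinf)·exp(-t/tau)."""

    I0: float
    Iinf: float
    tau_s: float


@dataclass
class EpochFeatures:
    """Per-K-epoch features; ``defined`` is False when the epoch carries no
    measurable current (flat/negative traces), in which case numeric fields
    are NaN rather than raising."""

    label: str
    t_start_s: float
    baseline_pApF: float
    I_peak: float = math.nan
    t_peak_s: float = math.nan
    I_plateau: float = math.nan
    F_decay: float = math.nan
    k_init: float = math.nan
    exp_fit: ExpFit | None = None
    defined: bool = False

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "t_start_s": self.t_start_s,
            "baseline_pApF": self.baseline_pApF,
            "I_peak": self.I_peak,
            "t_peak_s": self.t_peak_s,
            "I_plateau": self.I_plateau,
            "F_decay": self.F_decay,
            "k_init": self.k_init,
            "defined": self.defined,
        }
        if self.exp_fit is not None:
            d["exp_fit"] = {
                "I0": self.exp_fit.I0,
                "Iinf": self.exp_fit.Iinf,
                "tau_s": self.exp_fit.tau_s,
            }
        return d


@dataclass
class FeatureSet:
    """Features for every K epoch of a protocol, in epoch order."""

    epochs: list[EpochFeatures]

    def defined(self) -> list[EpochFeatures]:
        return [f for f in self.epochs if f.defined]

    def to_dict(self) -> dict:
        return {"epochs": [f.to_dict() for f in self.epochs]}


# ----------------------------------------------------------------------
# Canonical protocols


def make_protocol(kind: str, **options) -> Protocol:
    """Build one of the canonical solution-switch timelines.

    kinds
    -----
    ``standard_k_pulse``
        10 s Na -> 12 s K (7 mM for 7 mM) -> 10 s Na.
    ``ca_elevation``
        K pulses flanking a short (default 3 s) 5 mM Ca episode, mimicking
        the reverse-exchange Ca-loading experiments.
    ``na_rescue``
        K pulses separated by a nominally Na-free incubation, mimicking the
        extracellular-Na rescue measurements.
    ``deoxyglucose_rundown``
        A train of K pulses (default 5) for run-down series.
    """
    if kind == "standard_k_pulse":
        na = options.pop("na_mM", 7.0)
        k = options.pop("k_mM", 7.0)
        pre = options.pop("pre_s", 10.0)
        kdur = options.pop("k_duration_s", 12.0)
        post = options.pop("post_s", 10.0)
        tau = options.pop("switch_tau_s", 0.1)
        _reject_extra(kind, options)
        epochs = (
            Epoch("na_pre", 0.0, pre, Na_mM=na),
            Epoch("k_on", pre, kdur, K_mM=k),
            Epoch("na_post", pre + kdur, post, Na_mM=na),
        )
        return Protocol(epochs, switch_tau_s=tau)

    if kind == "ca_elevation":
        na = options.pop("na_mM", 7.0)
        k = options.pop("k_mM", 7.0)
        ca = options.pop("ca_mM", 5.0)
        pre = options.pop("pre_s", 10.0)
        kdur = options.pop("k_duration_s", 12.0)
        gap = options.pop("gap_s", 5.0)
        cadur = options.pop("ca_duration_s", 3.0)
        recovery = options.pop("recovery_s", 15.0)
        tau = options.pop("switch_tau_s", 0.1)
        _reject_extra(kind, options)
        t = 0.0
        epochs = []
        for label, dur, kw in (
            ("na_pre", pre, {"Na_mM": na}),
            ("k_pre", kdur, {"K_mM": k}),
            ("na_gap", gap, {"Na_mM": na}),
            ("ca_episode", cadur, {"Ca_mM": ca, "ca_episode": True}),
            ("na_recovery", recovery, {"Na_mM": na}),
            ("k_post", kdur, {"K_mM": k}),
            ("na_post", pre, {"Na_mM": na}),
        ):
            epochs.append(Epoch(label, t, dur, **kw))
            t += dur
        return Protocol(tuple(epochs), switch_tau_s=tau)

    if kind == "na_rescue":
        k = options.pop("k_mM", 5.0)
        na = options.pop("na_mM", 5.0)
        free_s = options.pop("na_free_s", 20.0)
        kdur = options.pop("k_duration_s", 12.0)
        tau = options.pop("switch_tau_s", 0.1)
        _reject_extra(kind, options)
        t = 0.0
        epochs = []
        for label, dur, kw in (
            ("na_pre", 10.0, {"Na_mM": na}),
            ("k_control", kdur, {"K_mM": k}),
            ("na_free", free_s, {}),
            ("k_test", kdur, {"K_mM": k}),
            ("na_post", 10.0, {"Na_mM": na}),
        ):
            epochs.append(Epoch(label, t, dur, **kw))
            t += dur
        return Protocol(tuple(epochs), switch_tau_s=tau)

    if kind == "deoxyglucose_rundown":
        n = int(options.pop("n_pulses", 5))
        na = options.pop("na_mM", 7.0)
        k = options.pop("k_mM", 7.0)
        kdur = options.pop("k_duration_s", 10.0)
        rest = options.pop("rest_s", 20.0)
        tau = options.pop("switch_tau_s", 0.1)
        _reject_extra(kind, options)
        if n < 1:
            raise ValidationError("n_pulses must be >= 1")
        t = 0.0
        epochs = [Epoch("na_pre", t, rest, Na_mM=na)]
        t += rest
        for i in range(n):
            epochs.append(Epoch(f"k_{i}", t, kdur, K_mM=k))
            t += kdur
            epochs.append(Epoch(f"rest_{i}", t, rest, Na_mM=na))
            t += rest
        return Protocol(tuple(epochs), switch_tau_s=tau)

    raise ValidationError(f"unknown protocol kind {kind!r}")


def _reject_extra(kind: str, options: dict):
    if options:
        raise ValidationError(f"unknown option(s) for {kind!r}: {sorted(options)}")


def apply_switch_filter(trace: Trace, tau_s: float) -> Trace:
    """First-order low-pass with the solution-switch time constant.

    Solution exchange around the myocyte is not instantaneous; filtering
    the emitted current with the switch time constant suppresses
    sub-switch-time transients (e.g. state-redistribution spikes of the
    cycle simulator) that the recording could not resolve.
    """
    if tau_s <= 0:
        return trace
    dt = trace.dt
    alpha = 1.0 - math.exp(-dt / tau_s)
    out = np.empty_like(trace.i_pApF)
    acc = trace.i_pApF[0]
    for i, v in enumerate(trace.i_pApF):
        acc += alpha * (v - acc)
        out[i] = acc
    return replace(trace, i_pApF=out)


# ----------------------------------------------------------------------
# Feature extraction


def extract_features(
    trace: Trace,
    protocol: Protocol,
    t_plateau: float = 10.0,
    peak_window_s: float = 0.5,
    baseline_window_s: float = 1.0,
    plateau_halfwidth_s: float = 0.25,
) -> FeatureSet:
    """Measure per-K-epoch features of a current trace.

    The peak is the maximum baseline-subtracted current within the first
    ``peak_window_s`` of the epoch (currents activate within solution-switch
    times, so the peak sits at the epoch front).  The baseline is the mean
    current over the ``baseline_window_s`` preceding the epoch.  The plateau
    is a short mean around ``t_plateau`` (epoch-relative) for noise
    robustness.  The decay from the detected peak to the epoch end is fitted
    to a single exponential with the asymptote bounded at >= 0, and the
    initial fractional decay rate is ``k_init = (I0 - Iinf)/(tau·I0)``.

    Epochs without measurable current yield ``defined=False`` features, not
    an exception.
    """
    if t_plateau <= 0:
        raise ValidationError("t_plateau must be > 0")
    if trace.time_s.size < 2:
        raise ValidationError("trace too short for feature extraction")
    if trace.time_s[0] > protocol.start_s + 1e-9 or trace.time_s[-1] < protocol.end_s - trace.dt - 1e-9:
        raise ValidationError("trace does not cover the protocol")

    out: list[EpochFeatures] = []
    t = trace.time_s
    y = trace.i_pApF
    for ep in protocol.k_epochs():
        if t_plateau > ep.duration_s + 1e-9:
            raise ValidationError(
                f"t_plateau={t_plateau:g} s exceeds K-epoch duration {ep.duration_s:g} s"
            )
        base_mask = trace.window(ep.start_s - baseline_window_s, ep.start_s)
        baseline = float(np.mean(y[base_mask])) if base_mask.any() else 0.0
        feats = EpochFeatures(label=ep.label, t_start_s=ep.start_s, baseline_pApF=baseline)

        peak_mask = trace.window(ep.start_s, ep.start_s + peak_window_s)
        if not peak_mask.any():
            out.append(feats)
            continue
        yw = y[peak_mask] - baseline
        i_pk = int(np.argmax(yw))
        I_peak = float(yw[i_pk])
        t_peak = float(t[peak_mask][i_pk])
        if not (I_peak > 0):
            out.append(feats)
            continue

        pl_mask = trace.window(
            ep.start_s + t_plateau - plateau_halfwidth_s,
            min(ep.start_s + t_plateau + plateau_halfwidth_s, ep.end_s),
        )
        I_plateau = float(np.mean(y[pl_mask]) - baseline) if pl_mask.any() else math.nan

        feats.I_peak = I_peak
        feats.t_peak_s = t_peak
        feats.I_plateau = I_plateau
        feats.F_decay = 1.0 - I_plateau / I_peak
        feats.defined = True

        fit_mask = (t >= t_peak - 1e-12) & (t < ep.end_s - 1e-12)
        tf = t[fit_mask] - t_peak
        yf = y[fit_mask] - baseline
        fit = _fit_single_exponential(tf, yf, I_peak, I_plateau, ep.duration_s)
        if fit is not None:
            feats.exp_fit = fit
            if fit.I0 > 0 and fit.tau_s > 0:
                feats.k_init = (fit.I0 - fit.Iinf) / (fit.tau_s * fit.I0)
        out.append(feats)
    return FeatureSet(out)


def _fit_single_exponential(
    tf: np.ndarray, yf: np.ndarray, I_peak: float, I_plateau: float, duration: float
) -> ExpFit | None:
    if tf.size < 4:
        return None

    def model(tt, i0, iinf, tau):
        return iinf + (i0 - iinf) * np.exp(-tt / tau)

    iinf0 = max(I_plateau if math.isfinite(I_plateau) else 0.0, 0.0)
    p0 = (max(I_peak, 1e-12), iinf0, max(duration / 4.0, 1e-3))
    try:
        popt, _ = curve_fit(
            model,
            tf,
            yf,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return None
    return ExpFit(I0=float(popt[0]), Iinf=float(popt[1]), tau_s=float(popt[2]))
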