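"""Measurement-error variance from percent-recovery quality-control data.

A recovery experiment measures a paired spiked / unspiked serum sample and a
gold-standard sample (the spike amount ``a`` in pure solvent).  The percent
recovery compares the recovered spike, i.e. the difference between the spiked
and unspiked measurements, with the gold standard:

    Q = [(c + a) e^{sigma eps_s} - c e^{sigma eps}] / [a e^{sigma eps_g}]

where ``c`` is the true sample concentration and the three epsilons are
independent standard normals — each measurement carries the same multiplicative
log-normal error, which is exactly an additive normal error with variance
sigma^2 on the log scale.  A first-order (delta-method) expansion of Q around
eps = 0 gives

    Var(Q) ≈ sigma^2 * g(c, a),   g(c, a) = (c/a)^2 + ((c+a)/a)^2 + 1,

so the observed SD of the recoveries identifies sigma^2 = SD(Q)^2 / g(c, a).
`simulate_recovery` is a Monte-Carlo simulator of the same experiment, used as
an internal oracle for the delta approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class RecoveryQC:
    """Per-exposure recovery-experiment summaries.

    ``sd_recovery`` is on the fraction scale (0.157, not 15.7%); ``c`` is the
    mean sample concentration and ``spike`` the spike amount, both on the same
    original (e.g. ppb) scale.
    """

    sd_recovery: np.ndarray
    c: np.ndarray
    spike: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sd_recovery = np.atleast_1d(np.asarray(self.sd_recovery, dtype=float))
        self.c = np.broadcast_to(
            np.asarray(self.c, dtype=float), self.sd_recovery.shape
        ).copy()
        self.spike = np.broadcast_to(
            np.asarray(self.spike, dtype=float), self.sd_recovery.shape
        ).copy()
        if np.any(self.sd_recovery < 0):
            raise ValueError("sd_recovery must be non-negative")
        if np.any(self.c < 0):
            raise ValueError("mean concentrations must be non-negative")
        if np.any(self.spike <= 0):
            raise ValueError("spike amount must be positive")
        if not self.names:
            self.names = [f"x{p + 1}" for p in range(len(self.sd_recovery))]


@dataclass
class MeasurementErrorSpec:
    """Known diagonal error covariance: per-exposure variances on the log scale."""

    sigma2: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if np.any(self.sigma2 < 0):
            raise ValueError("error variances must be non-negative")

    @property
    def P(self) -> int:
        return len(self.sigma2)


def g_factor(c, spike):
    """Delta-method variance inflation g(c, a) = (c/a)^2 + ((c+a)/a)^2 + 1."""
    c = np.asarray(c, dtype=float)
    spike = np.asarray(spike, dtype=float)
    return (c / spike) ** 2 + ((c + spike) / spike) ** 2 + 1.0


def estimate_sigma2(qc: RecoveryQC) -> MeasurementErrorSpec:
    """Invert the delta-method relation: sigma^2_p = sd_recovery_p^2 / g(c_p, a_p)."""
    return MeasurementErrorSpec(sigma2=qc.sd_recovery**2 / g_factor(qc.c, qc.spike))


def simulate_recovery(
    sigma: float, c: float, spike: float, n_reps: int, seed=None
) -> float:
    """Monte-Carlo SD of the percent recovery under the log-normal error model.

    Draws independent standard-normal errors for the unspiked, spiked and gold
    measurements and returns the sample SD of
    Q = [(c+a) e^{sigma eps_s} - c e^{sigma eps}] / [a e^{sigma eps_g}].
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if spike <= 0:
        raise ValueError("spike amount must be positive")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((3, n_reps))
    q = ((c + spike) * np.exp(sigma * eps[0]) - c * np.exp(sigma * eps[1])) / (
        spike * np.exp(sigma * eps[2])
    )
    return float(np.std(q, ddof=1))


def scale(spec: MeasurementErrorSpec, factor: float) -> MeasurementErrorSpec:
    """Multiply every error variance by ``factor`` (sensitivity-analysis knob)."""
    if factor < 0:
        raise ValueError("scale factor must be non-negative")
    return replace(
        spec, sigma2=spec.sigma2 * factor, scale_factor=spec.scale_factor * factor
    )


def read_qc(path) -> RecoveryQC:
    """Read a QC CSV: columns name, sd_recovery, mean_concentration, spike."""
    df = pd.read_csv(path)
    return RecoveryQC(
        sd_recovery=df["sd_recovery"].to_numpy(float),
        c=df["mean_concentration"].to_numpy(float),
        spike=df["spike"].to_numpy(float),
        names=list(df["name"]) if "name" in df.columns else [],
    )
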