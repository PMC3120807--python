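"""Synthetic matched case-control studies with the model's exact structure.

The generator draws data from the same three-layer mechanism the inference
assumes, so parameter-recovery experiments are meaningful end to end:

* set-level true-exposure means around a grand mean (between-set covariance),
  subjects around their set mean (within-set covariance);
* the case within each set chosen with probability proportional to
  exp(x' beta + z' delta) — exactly the conditional-logistic law;
* surrogate exposures = true exposures + independent normal error per
  exposure (classical, non-differential by construction).

Confounders (continuous and binary) are tied to the exposures only through a
weak shared set-level factor, keeping exposure-confounder correlations small
(|corr| well under 0.18 at the defaults).

Defaults emulate the motivating perfluorinated-acid study's shape: 96 matched
sets of size 2-4 totalling 271 subjects, three log-scale exposures, four
confounders (three continuous, one binary), weak true odds ratios, and
moderate measurement error (error SD about 0.3 of the total exposure SD).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MatchedStudy, RawConcentrationTable


def _equicorr(P: int, rho: float) -> np.ndarray:
    return (1 - rho) * np.eye(P) + rho * np.ones((P, P))


_DEFAULT_SIZE_COUNTS = {2: 34, 3: 45, 4: 17}  # 96 sets, 271 subjects


@dataclass
class GeneratorConfig:
    """Ground-truth parameters and design shape for one synthetic study."""

    n_sets: int = 96
    size_counts: dict = field(default_factory=lambda: dict(_DEFAULT_SIZE_COUNTS))
    size_probs: dict | None = None  # alternative to exact counts
    beta: np.ndarray = field(
        default_factory=lambda: np.log(np.array([0.9, 0.8, 1.3]))
    )
    delta: np.ndarray | None = None  # defaults to zeros(K)
    mu: np.ndarray | None = None  # defaults to zeros(P)
    V_W: np.ndarray | None = None  # defaults to 0.6 * equicorr(0.3)
    V_B: np.ndarray | None = None  # defaults to 0.4 * equicorr(0.3)
    sigma2: np.ndarray | None = None  # defaults to 0.09 per exposure
    n_continuous_confounders: int = 3
    binary_confounder: bool = True
    factor_weight: float = 0.3  # share of between-set variation from the shared factor
    confounder_loading: float = 0.35
    seed: int = 0

    def resolved(self) -> "GeneratorConfig":
        beta = np.atleast_1d(np.asarray(self.beta, float))
        P = len(beta)
        K = self.n_continuous_confounders + int(self.binary_confounder)
        out = GeneratorConfig(
            n_sets=self.n_sets,
            size_counts=dict(self.size_counts) if self.size_probs is None else {},
            size_probs=dict(self.size_probs) if self.size_probs else None,
            beta=beta,
            delta=np.zeros(K) if self.delta is None else np.atleast_1d(np.asarray(self.delta, float)),
            mu=np.zeros(P) if self.mu is None else np.asarray(self.mu, float),
            V_W=0.6 * _equicorr(P, 0.3) if self.V_W is None else np.asarray(self.V_W, float),
            V_B=0.4 * _equicorr(P, 0.3) if self.V_B is None else np.asarray(self.V_B, float),
            sigma2=np.full(P, 0.09) if self.sigma2 is None else np.atleast_1d(np.asarray(self.sigma2, float)),
            n_continuous_confounders=self.n_continuous_confounders,
            binary_confounder=self.binary_confounder,
            factor_weight=self.factor_weight,
            confounder_loading=self.confounder_loading,
            seed=self.seed,
        )
        if out.n_sets < 2:
            raise ValueError("need at least 2 matched sets")
        if len(out.delta) != K:
            raise ValueError("delta length must match the number of confounders")
        if np.any(out.sigma2 < 0):
            raise ValueError("error variances must be non-negative")
        for V, name in ((out.V_W, "V_W"), (out.V_B, "V_B")):
            if V.shape != (P, P):
                raise ValueError(f"{name} must be {P}x{P}")
            np.linalg.cholesky(V)  # raises if not positive definite
        if out.size_probs is not None:
            p = np.array(list(out.size_probs.values()), float)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("size probabilities must sum to 1")
        return out


@dataclass
class SyntheticStudy:
    """A generated study together with its ground truth."""

    study: MatchedStudy
    X: np.ndarray  # (S, P) true exposures
    M: np.ndarray  # (N, P) true set-level means
    config: GeneratorConfig
    case_position: np.ndarray | None = None  # pre-reordering index of each case

    def truth(self) -> dict:
        c = self.config
        return {
            "beta": np.asarray(c.beta).tolist(),
            "delta": np.asarray(c.delta).tolist(),
            "mu": np.asarray(c.mu).tolist(),
            "V_W": np.asarray(c.V_W).tolist(),
            "V_B": np.asarray(c.V_B).tolist(),
            "sigma2": np.asarray(c.sigma2).tolist(),
            "seed": c.seed,
        }


def _draw_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.size_probs is not None:
        sizes = rng.choice(
            list(cfg.size_probs), size=cfg.n_sets, p=list(cfg.size_probs.values())
        ).astype(int)
    else:
        counts = cfg.size_counts
        if sum(counts.values()) != cfg.n_sets:
            raise ValueError("size_counts must sum to n_sets")
        sizes = np.repeat(list(counts), list(counts.values()))
        rng.shuffle(sizes)
    if np.any(sizes < 2):
        raise ValueError("set sizes must be at least 2")
    return sizes


def generate(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Draw one synthetic study from the generator's three-layer mechanism."""
    cfg = (config or GeneratorConfig()).resolved()
    if seed is not None:
        cfg.seed = int(seed)
    rng = np.random.default_rng(cfg.seed)
    P = len(cfg.beta)
    K = len(cfg.delta)
    sizes = _draw_sizes(cfg, rng)
    N = cfg.n_sets
    S = int(sizes.sum())
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    set_index = np.repeat(np.arange(N), sizes)

    L_B = np.linalg.cholesky(cfg.V_B)
    L_W = np.linalg.cholesky(cfg.V_W)
    r = cfg.factor_weight
    u = np.ones(P) / np.sqrt(P)

    # set-level shared factor ties exposures and confounders together weakly
    f = rng.standard_normal(N)
    eps_B = np.sqrt(1 - r**2) * rng.standard_normal((N, P)) + r * np.outer(f, u)
    M = cfg.mu + eps_B @ L_B.T
    X = M[set_index] + rng.standard_normal((S, P)) @ L_W.T

    load = cfg.confounder_loading
    Z = np.zeros((S, K))
    for k in range(cfg.n_continuous_confounders):
        Z[:, k] = load * f[set_index] + np.sqrt(1 - load**2) * rng.standard_normal(S)
    if cfg.binary_confounder:
        p_bin = 1.0 / (1.0 + np.exp(-1.2 * load * f[set_index]))
        Z[:, K - 1] = (rng.random(S) < p_bin).astype(float)

    # conditional-logistic case assignment: one case per set, chosen with
    # probability proportional to exp(x'beta + z'delta)
    eta = X @ cfg.beta + (Z @ cfg.delta if K else 0.0)
    case_position = np.zeros(N, dtype=int)
    for i in range(N):
        sl = slice(offsets[i], offsets[i] + sizes[i])
        e = eta[sl]
        w = np.exp(e - e.max())
        case = rng.choice(sizes[i], p=w / w.sum())
        case_position[i] = case
        if case != 0:
            order = np.r_[case, [j for j in range(sizes[i]) if j != case]]
            X[sl] = X[sl][order]
            Z[sl] = Z[sl][order]
            eta[sl] = eta[sl][order]

    U = rng.standard_normal((S, P)) * np.sqrt(cfg.sigma2)
    W = X + U

    study = MatchedStudy(
        set_ids=[f"set{i + 1:03d}" for i in range(N)],
        sizes=sizes,
        W=W,
        Z=Z,
        exposure_names=[f"x{p + 1}" for p in range(P)],
        confounder_names=[f"z{k + 1}" for k in range(cfg.n_continuous_confounders)]
        + (["z_bin"] if cfg.binary_confounder else []),
    )
    return SyntheticStudy(
        study=study, X=X, M=M, config=cfg, case_position=case_position
    )


def censor(
    synth: SyntheticStudy, lod, m=None
) -> tuple[RawConcentrationTable, np.ndarray]:
    """Back-transform surrogates to concentrations and flag values below LOD.

    Returns a raw concentration table (ready for LOD/2 substitution and the
    log-molar transform) and the realized per-exposure censoring fraction.
    """
    W = synth.study.W
    P = W.shape[1]
    m = np.ones(P) if m is None else np.broadcast_to(np.asarray(m, float), (P,)).copy()
    lod = np.broadcast_to(np.asarray(lod, float), (P,)).copy()
    conc = m * np.exp(W)
    nondetect = conc < lod
    table = RawConcentrationTable(
        values=conc,
        nondetect=nondetect,
        lod=np.where(lod > 0, lod, np.finfo(float).tiny),
        m=m,
        exposure_names=list(synth.study.exposure_names),
    )
    return table, nondetect.mean(axis=0)


def to_csv(synth: SyntheticStudy, path, truth_path=None) -> None:
    """Write the observed study as a CSV (and optionally the ground truth JSON)."""
    st = synth.study
    df = pd.DataFrame(st.W, columns=st.exposure_names)
    for k, name in enumerate(st.confounder_names):
        df[name] = st.Z[:, k]
    df.insert(0, "case", st.is_case)
    df.insert(0, "set", np.asarray(st.set_ids)[st.set_index])
    df.to_csv(path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(synth.truth(), fh, indent=2)
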