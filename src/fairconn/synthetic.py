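"""Synthetic multi-group, multi-site connectome datasets with known ground truth.

Emulates the statistical structure that the fairness audit assumes of its
inputs: per-subject vectorized functional-connectivity (FC) features drawn
from a latent low-rank-plus-diagonal covariance shared across groups,
behavioral scores generated from group-specific linear edge-weight patterns,
confounds that load on both FC and behavior, site and family grouping, and
configurable group mean shift / variance ratio of the behavioral score.

Group differences live only in the weight patterns (their correlation is the
``pattern_similarity`` dial), the behavioral mean shift, the variance ratio,
and the confound loadings — so the bias mechanism under study
(association-pattern divergence) is isolated from nuisance distribution
shift, which the confound loadings re-introduce controllably.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .qc import RunTimeseries, devectorize_rsfc, vectorize_rsfc

__all__ = [
    "ConfoundSpec",
    "SyntheticConfig",
    "SubjectRecord",
    "SyntheticDataset",
    "generate_dataset",
    "generate_suite",
    "generate_timeseries",
    "ground_truth_association",
    "MAJORITY",
    "MINORITY",
    "OTHER",
]

MAJORITY = "majority"
MINORITY = "minority"
OTHER = "other"

# Fixed stream offsets: every random sub-stream is seeded as
# default_rng([seed, STREAM_*, ...]) so streams never alias.
_STREAM_WEIGHTS = 1
_STREAM_COVARIANCE = 2
_STREAM_STRUCTURE = 3
_STREAM_FC = 4
_STREAM_CONFOUNDS = 5
_STREAM_NOISE = 6
_STREAM_TIMESERIES = 7


@dataclass(frozen=True)
class ConfoundSpec:
    """One confound variable and how it loads on behavior and FC.

    ``kind`` is ``continuous`` (standard normal) or ``binary``
    (Bernoulli(1/2), gender-like). The FC loading applies to a seeded random
    subset of edges of size ``fc_fraction * n_edges``.
    """

    name: str
    y_loading: float = 0.0
    fc_loading: float = 0.0
    fc_fraction: float = 0.1
    kind: str = "continuous"

    @property
    def variance(self) -> float:
        return 0.25 if self.kind == "binary" else 1.0


def default_confounds() -> tuple[ConfoundSpec, ...]:
    """Age-like, motion-like (continuous) and gender-like (binary) confounds."""
    return (
        ConfoundSpec("age", y_loading=0.2, fc_loading=0.02, fc_fraction=0.1),
        ConfoundSpec("mean_fd", y_loading=-0.2, fc_loading=0.02, fc_fraction=0.1),
        ConfoundSpec("gender", y_loading=0.2, fc_loading=0.0, kind="binary"),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic study population.

    The latent FC model is ``c = mu + B u + sqrt(diag_var) eps + L f`` with
    ``B`` a p×k loading matrix shared across groups, ``f`` the confound
    vector, and ``L`` the per-confound edge-loading matrix. Behavioral score:
    ``y = c·w_group + beta·f + shift·1[minority] + noise``.

    ``noise_sd`` is the majority-group noise SD; ``None`` sets it to the
    realized signal SD, i.e. population R² = 0.5. Minority noise is rescaled
    so Var(y_minority)/Var(y_majority) equals ``group_variance_ratio``
    exactly in population (skipped when noise_sd == 0, where the noiseless
    identity y = c·w takes precedence).
    """

    n_majority: int = 400
    n_minority: int = 100
    n_other: int = 0
    n_roi: int = 40
    n_sites: int = 5
    family_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    w_majority: np.ndarray | None = None
    w_minority: np.ndarray | None = None
    pattern_similarity: float = 1.0
    noise_sd: float | None = None
    confound_loadings: Sequence[ConfoundSpec] = field(default_factory=default_confounds)
    group_mean_shift: float = 0.0
    group_variance_ratio: float = 1.0
    frames_per_run: int = 100
    runs_per_subject: int = 2
    motion_params: Mapping[str, float] = field(
        default_factory=lambda: {
            "spike_rate": 0.05,
            "fd_base": 0.08,
            "fd_spike": 0.5,
            "dvars_base": 30.0,
            "dvars_spike": 60.0,
            "jitter": 0.02,
        }
    )
    latent_rank: int = 10
    latent_loading_sd: float = 0.05
    latent_diag_var: float = 0.01
    edge_mean: float = 0.1
    edge_mean_sd: float = 0.05
    seed: int = 0

    @property
    def n_edges(self) -> int:
        return self.n_roi * (self.n_roi - 1) // 2

    @property
    def n_subjects(self) -> int:
        return self.n_majority + self.n_minority + self.n_other

    def validate(self) -> None:
        for name in ("n_majority", "n_minority", "n_roi", "n_sites",
                     "frames_per_run", "runs_per_subject"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_other < 0:
            raise ValueError("n_other must be >= 0")
        if not -1.0 <= self.pattern_similarity <= 1.0:
            raise ValueError("pattern_similarity must be in [-1, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.group_variance_ratio <= 0:
            raise ValueError("group_variance_ratio must be > 0")
        probs = np.asarray(list(self.family_size_distribution.values()), float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("family_size_distribution must be a probability table")
        for w, name in ((self.w_majority, "w_majority"), (self.w_minority, "w_minority")):
            if w is not None and np.asarray(w).shape != (self.n_edges,):
                raise ValueError(
                    f"{name} has length {np.asarray(w).size}, expected "
                    f"{self.n_edges} edges for n_roi={self.n_roi}"
                )


@dataclass
class SubjectRecord:
    """One participant: FC vector, behavioral score, group, confounds, structure."""

    subject_id: str
    group: str
    site: int
    family: int
    fc: np.ndarray
    y: float
    confounds: dict[str, float]


@dataclass
class SyntheticDataset:
    """Generated population plus the generative truth.

    ``fc`` is subjects × edges (Fisher-z scale); ``scores`` maps behavior
    name → score vector; ``truth`` carries the weight vectors, noiseless
    scores and the config echo for oracle checks downstream.
    """

    config: SyntheticConfig
    subject_ids: list[str]
    groups: np.ndarray
    sites: np.ndarray
    families: np.ndarray
    confounds: "pd.DataFrame"
    fc: np.ndarray
    scores: dict[str, np.ndarray]
    truth: dict

    @property
    def y(self) -> np.ndarray:
        if len(self.scores) != 1:
            raise ValueError("dataset has multiple behaviors; index scores by name")
        return next(iter(self.scores.values()))

    @property
    def behaviors(self) -> list[str]:
        return list(self.scores)

    @property
    def n_subjects(self) -> int:
        return self.fc.shape[0]

    @property
    def subjects(self) -> list[SubjectRecord]:
        conf = self.confounds.to_dict("records")
        yname = self.behaviors[0]
        return [
            SubjectRecord(
                subject_id=self.subject_ids[i],
                group=str(self.groups[i]),
                site=int(self.sites[i]),
                family=int(self.families[i]),
                fc=self.fc[i],
                y=float(self.scores[yname][i]),
                confounds={k: float(v) for k, v in conf[i].items()},
            )
            for i in range(self.n_subjects)
        ]

    def table(self) -> "pd.DataFrame":
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.groups,
                "site": self.sites,
                "family": self.families,
            }
        )
        df = pd.concat([df, self.confounds.reset_index(drop=True)], axis=1)
        for name, vals in self.scores.items():
            df[name] = vals
        return df


# --------------------------------------------------------------------------
# generative internals


def _latent_model(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """(mu, B, diag_var) of the shared latent FC distribution, seeded."""
    rng = np.random.default_rng([config.seed, _STREAM_COVARIANCE])
    p = config.n_edges
    mu = config.edge_mean + config.edge_mean_sd * rng.standard_normal(p)
    B = config.latent_loading_sd * rng.standard_normal((p, config.latent_rank))
    return mu, B, config.latent_diag_var


def _make_weights(
    config: SyntheticConfig, stream: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-norm weight pair with Pearson correlation exactly
    ``pattern_similarity`` (zero-mean vectors make corr equal the cosine)."""
    if config.w_majority is not None and config.w_minority is not None:
        wa = np.asarray(config.w_majority, float)
        wb = np.asarray(config.w_minority, float)
        got = float(np.corrcoef(wa, wb)[0, 1])
        if abs(got - config.pattern_similarity) > 1e-6:
            raise ValueError(
                f"supplied weight vectors have correlation {got:.6f}, "
                f"pattern_similarity={config.pattern_similarity}"
            )
        return wa, wb
    rng = np.random.default_rng([config.seed, _STREAM_WEIGHTS, stream])
    p = config.n_edges
    g1 = rng.standard_normal(p)
    g2 = rng.standard_normal(p)
    g1 -= g1.mean()
    g2 -= g2.mean()
    u1 = g1 / np.linalg.norm(g1)
    v = g2 - (g2 @ u1) * u1
    u2 = v / np.linalg.norm(v)
    rho = config.pattern_similarity
    w_min = rho * u1 + np.sqrt(max(0.0, 1.0 - rho**2)) * u2
    return u1, w_min


def _confound_edge_loadings(config: SyntheticConfig) -> np.ndarray:
    """p × J matrix L: column j is confound j's edge-loading pattern."""
    rng = np.random.default_rng([config.seed, _STREAM_CONFOUNDS, 0])
    p = config.n_edges
    cols = []
    for spec in config.confound_loadings:
        col = np.zeros(p)
        if spec.fc_loading != 0.0:
            k = max(1, int(round(spec.fc_fraction * p)))
            idx = rng.choice(p, size=k, replace=False)
            col[idx] = spec.fc_loading
        else:
            rng.choice(p, size=1)  # keep stream alignment across specs
        cols.append(col)
    return np.column_stack(cols) if cols else np.zeros((p, 0))


def _structure(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(groups, families, sites). Families are group-homogeneous; each family
    sits wholly in one site, so family blocks never straddle sites."""
    rng = np.random.default_rng([config.seed, _STREAM_STRUCTURE])
    sizes = np.asarray(list(config.family_size_distribution.keys()), int)
    probs = np.asarray(list(config.family_size_distribution.values()), float)
    probs = probs / probs.sum()

    groups: list[str] = []
    families: list[int] = []
    sites: list[int] = []
    fam_id = 0
    for gname, n in (
        (MAJORITY, config.n_majority),
        (MINORITY, config.n_minority),
        (OTHER, config.n_other),
    ):
        remaining = n
        while remaining > 0:
            size = int(rng.choice(sizes, p=probs))
            size = min(size, remaining)
            site = int(rng.integers(config.n_sites))
            groups.extend([gname] * size)
            families.extend([fam_id] * size)
            sites.extend([site] * size)
            fam_id += 1
            remaining -= size
    return np.asarray(groups), np.asarray(families), np.asarray(sites)


def _draw_confounds(config: SyntheticConfig, n: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, _STREAM_CONFOUNDS, 1])
    cols = []
    for spec in config.confound_loadings:
        if spec.kind == "binary":
            cols.append(rng.integers(0, 2, size=n).astype(float))
        else:
            cols.append(rng.standard_normal(n))
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def _signal_variance(config: SyntheticConfig, w: np.ndarray) -> float:
    """Population Var(c·w + beta·f) under the generative model."""
    mu, B, d = _latent_model(config)
    L = _confound_edge_loadings(config)
    beta = np.asarray([s.y_loading for s in config.confound_loadings], float)
    fvar = np.asarray([s.variance for s in config.confound_loadings], float)
    base = float((B.T @ w) @ (B.T @ w) + d * (w @ w))
    if L.shape[1]:
        total_load = L.T @ w + beta
        base += float(total_load @ (fvar * total_load))
    return base


def _group_noise_sds(config: SyntheticConfig) -> dict[str, float]:
    w_maj, w_min = _make_weights(config)
    s_maj = _signal_variance(config, w_maj)
    s_min = _signal_variance(config, w_min)
    noise_maj = np.sqrt(s_maj) if config.noise_sd is None else float(config.noise_sd)
    if noise_maj == 0.0:
        return {MAJORITY: 0.0, MINORITY: 0.0, OTHER: 0.0}
    var_maj = s_maj + noise_maj**2
    noise_min_sq = config.group_variance_ratio * var_maj - s_min
    if noise_min_sq < 0:
        raise ValueError(
            "group_variance_ratio unattainable: minority signal variance "
            f"{s_min:.4f} exceeds the target total variance "
            f"{config.group_variance_ratio * var_maj:.4f}"
        )
    return {MAJORITY: noise_maj, MINORITY: float(np.sqrt(noise_min_sq)), OTHER: noise_maj}


def _generate_scores(
    config: SyntheticConfig,
    fc: np.ndarray,
    confounds: np.ndarray,
    groups: np.ndarray,
    behavior_stream: int,
    weights: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, dict]:
    w_maj, w_min = weights
    beta = np.asarray([s.y_loading for s in config.confound_loadings], float)
    noise_sds = _group_noise_sds(config)
    rng = np.random.default_rng([config.seed, _STREAM_NOISE, behavior_stream])

    w_of = {MAJORITY: w_maj, MINORITY: w_min, OTHER: w_maj}
    signal = np.empty(fc.shape[0])
    for g, w in w_of.items():
        m = groups == g
        if m.any():
            signal[m] = fc[m] @ w
    noiseless = signal.copy()
    if confounds.shape[1]:
        noiseless = noiseless + confounds @ beta
    noiseless = noiseless + np.where(groups == MINORITY, config.group_mean_shift, 0.0)

    eps = rng.standard_normal(fc.shape[0])
    sd = np.asarray([noise_sds[g] for g in groups])
    y = noiseless + sd * eps
    truth = {
        "w_majority": w_maj,
        "w_minority": w_min,
        "noiseless_y": noiseless,
        "noise_sd_by_group": noise_sds,
    }
    return y, noiseless, truth


def _generate_fc(config: SyntheticConfig, confounds: np.ndarray) -> np.ndarray:
    mu, B, d = _latent_model(config)
    rng = np.random.default_rng([config.seed, _STREAM_FC])
    n, p = config.n_subjects, config.n_edges
    fc = (
        rng.standard_normal((n, B.shape[1])) @ B.T
        + np.sqrt(d) * rng.standard_normal((n, p))
        + mu
    )
    L = _confound_edge_loadings(config)
    if L.shape[1]:
        fc = fc + confounds @ L.T
    return fc


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one single-behavior dataset; bit-identical given ``config.seed``."""
    return generate_suite(config, {"y": config.pattern_similarity})


def generate_suite(
    config: SyntheticConfig,
    behaviors: Mapping[str, float],
) -> SyntheticDataset:
    """Generate a dataset with several behaviors over shared FC.

    ``behaviors`` maps behavior name → pattern_similarity for that behavior's
    weight pair. All behaviors share the FC features, confounds and
    group/site/family structure; each gets its own seeded weight pair and
    noise stream.
    """
    import pandas as pd

    config.validate()
    groups, families, sites = _structure(config)
    confound_mat = _draw_confounds(config, config.n_subjects)
    fc = _generate_fc(config, confound_mat)

    scores: dict[str, np.ndarray] = {}
    truth: dict = {"config": config, "behaviors": {}}
    for b_idx, (name, rho) in enumerate(behaviors.items()):
        bcfg = dataclasses.replace(config, pattern_similarity=float(rho))
        weights = _make_weights(bcfg, stream=b_idx)
        y, noiseless, b_truth = _generate_scores(
            bcfg, fc, confound_mat, groups, b_idx, weights
        )
        scores[name] = y
        b_truth["pattern_similarity"] = float(rho)
        truth["behaviors"][name] = b_truth

    conf_df = pd.DataFrame(
        confound_mat, columns=[s.name for s in config.confound_loadings]
    )
    ids = [f"sub-{i:05d}" for i in range(config.n_subjects)]
    return SyntheticDataset(
        config=config,
        subject_ids=ids,
        groups=groups,
        sites=sites,
        families=families,
        confounds=conf_df,
        fc=fc,
        scores=scores,
        truth=truth,
    )


def ground_truth_association(config: SyntheticConfig, group: str) -> np.ndarray:
    """Population covariance between each FC edge and y for ``group``.

    Under the generative model cov(c, y) = Σ0·w + L Σf Lᵀ w + L Σf β, where
    Σ0 = BBᵀ + dI is the latent edge covariance, L the confound edge
    loadings, Σf the (diagonal) confound covariance and β the confound
    y-loadings. The mean shift and noise do not enter a covariance.
    """
    config.validate()
    w_maj, w_min = _make_weights(config)
    w_of = {MAJORITY: w_maj, MINORITY: w_min, OTHER: w_maj}
    if group not in w_of:
        raise ValueError(f"unknown group label {group!r}")
    w = w_of[group]
    _, B, d = _latent_model(config)
    out = B @ (B.T @ w) + d * w
    L = _confound_edge_loadings(config)
    if L.shape[1]:
        beta = np.asarray([s.y_loading for s in config.confound_loadings], float)
        fvar = np.asarray([s.variance for s in config.confound_loadings], float)
        out = out + L @ (fvar * (L.T @ w + beta))
    return out


# --------------------------------------------------------------------------
# time-series emission


def _nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection to a positive-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, floor, None)
    R2 = (vecs * vals) @ vecs.T
    dscale = 1.0 / np.sqrt(np.diag(R2))
    R2 = R2 * np.outer(dscale, dscale)
    np.fill_diagonal(R2, 1.0)
    return R2


def generate_timeseries(
    config: SyntheticConfig, subject: SubjectRecord
) -> list[RunTimeseries]:
    """Per-run Gaussian ROI series whose empirical correlation converges to the
    subject's assigned FC, with spike-contaminated FD/DVARS traces.

    The subject's Fisher-z FC vector is mapped to correlation space (tanh),
    projected to the nearest positive-definite correlation matrix, and used
    as the sampling covariance. Spike frames occur independently at
    ``motion_params['spike_rate']`` per frame; a rate of 0 keeps every FD
    below any positive threshold.
    """
    if config.frames_per_run < 10:
        raise ValueError("frames_per_run must be >= 10")
    mp = dict(config.motion_params)
    R = devectorize_rsfc(np.tanh(subject.fc), diagonal=1.0)
    R = _nearest_correlation(R)
    chol = np.linalg.cholesky(R)
    sub_index = int(subject.subject_id.split("-")[-1])

    runs = []
    for r in range(config.runs_per_subject):
        rng = np.random.default_rng(
            [config.seed, _STREAM_TIMESERIES, sub_index, r]
        )
        F = config.frames_per_run
        signal = rng.standard_normal((F, config.n_roi)) @ chol.T
        spikes = rng.random(F) < mp.get("spike_rate", 0.0)
        jit = mp.get("jitter", 0.02)
        fd = np.abs(mp.get("fd_base", 0.08) + jit * rng.standard_normal(F))
        dvars = np.abs(
            mp.get("dvars_base", 30.0) + 100 * jit * rng.standard_normal(F)
        )
        fd[spikes] += mp.get("fd_spike", 0.5)
        dvars[spikes] += mp.get("dvars_spike", 60.0)
        runs.append(RunTimeseries(signal=signal, fd=fd, dvars=dvars))
    return runs


def assigned_fc_correlation(config: SyntheticConfig, subject: SubjectRecord) -> np.ndarray:
    """The positive-definite correlation matrix actually sampled by
    :func:`generate_timeseries` (assigned FC after the PD projection)."""
    R = devectorize_rsfc(np.tanh(subject.fc), diagonal=1.0)
    return _nearest_correlation(R)
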