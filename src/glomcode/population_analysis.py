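"""Core population-response analytics.

Covers the trial-aligned response pipeline: dF/F conversion, peak amplitude
extraction, within-stimulus trial correlation matrices (noise correlations),
complete-linkage functional clustering of tuning, extraction of the shared
trial-to-trial gain factor (PC1 of mean-removed amplitudes), Spearman
behavior-amplitude correlation with Holm (step-down Bonferroni) control, and
multinomial-logistic-regression stimulus decoding with the within-stimulus
trial-shuffle control that removes noise correlations while exactly
preserving per-stimulus, per-glomerulus means and variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.linear_model import LogisticRegression

from .synthetic_population import TrialTensor, TuningMatrix

__all__ = [
    "AmplitudeMatrix",
    "CorrelationMatrix",
    "DecodingResult",
    "compute_dff",
    "peak_amplitudes",
    "trial_correlations",
    "cluster_tuning",
    "shared_gain",
    "behavior_correlation",
    "behavior_correlation_test",
    "decode",
    "shuffle_trials",
]

logger = logging.getLogger(__name__)


@dataclass
class AmplitudeMatrix:
    """Peak dF/F per trial (rows) and glomerulus (columns)."""

    values: np.ndarray  # trials x glomeruli
    labels: np.ndarray  # stimulus id per trial
    z_scored: bool = False
    glomerulus_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("amplitudes must be finite")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # glomeruli x glomeruli
    n_trials_used: int
    aggregation: str = "averaged"  # or "per-stimulus"

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        diag = np.diag(v)
        if not np.allclose(diag[np.isfinite(diag)], 1.0):
            raise ValueError("correlation matrix must have unit diagonal")

    def mean_offdiagonal(self) -> float:
        mask = ~np.eye(self.values.shape[0], dtype=bool)
        return float(np.nanmean(self.values[mask]))


@dataclass
class DecodingResult:
    overall_accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray  # classes x classes, row-normalised
    classes: np.ndarray
    n_iterations: int
    shuffled: bool = False


def compute_dff(
    raw_f: np.ndarray, time: np.ndarray, baseline_window: tuple[float, float]
) -> np.ndarray:
    """(F - F0) / F0 per glomerulus per trial; F0 = mean F in the baseline window.

    The baseline window must precede stimulus onset (time 0).
    """
    t0, t1 = baseline_window
    if t1 > 0:
        raise ValueError("baseline window must precede stimulus onset")
    mask = (time >= t0) & (time <= t1)
    if not mask.any():
        raise ValueError("empty baseline window")
    f0 = raw_f[..., mask].mean(axis=-1, keepdims=True)
    bad = f0 <= 0
    if bad.any():
        g, t = np.argwhere(bad[..., 0])[0]
        raise ValueError(f"non-positive baseline F0 for glomerulus {g}, trial {t}")
    return (raw_f - f0) / f0


def peak_amplitudes(
    tensor: TrialTensor, response_window: tuple[float, float] | None = None
) -> AmplitudeMatrix:
    """Maximum dF/F within the response window per glomerulus per trial.

    The default window is the stimulus epoch plus the tail (to catch late
    calcium peaks).
    """
    if response_window is None:
        response_window = (0.0, tensor.epoch[1] + tensor.epoch[2])
    t0, t1 = response_window
    mask = (tensor.time >= t0) & (tensor.time <= t1)
    if not mask.any():
        raise ValueError("empty response window")
    peaks = tensor.dff[:, :, mask].max(axis=2)  # glomeruli x trials
    return AmplitudeMatrix(
        values=peaks.T,
        labels=np.asarray(tensor.labels),
        glomerulus_names=tensor.glomerulus_names,
    )


def trial_correlations(amps: AmplitudeMatrix, per_stimulus: bool = True) -> CorrelationMatrix:
    """Pairwise Pearson noise correlations of trial amplitudes.

    Correlations are computed across trials within each stimulus, then
    averaged across stimuli (``per_stimulus=True``, the default) or computed
    on the pooled trials.  Glomeruli with zero variance within a stimulus get
    undefined correlations for that stimulus; those entries are excluded from
    the average (logged).
    """
    G = amps.n_glomeruli
    if per_stimulus:
        mats = []
        for s in np.unique(amps.labels):
            block = amps.values[amps.labels == s]
            if block.shape[0] < 3:
                raise ValueError(f"stimulus {s!r} has fewer than 3 trials")
            sd = block.std(axis=0)
            if np.any(sd == 0):
                logger.warning(
                    "stimulus %r: zero-variance glomeruli %s excluded from correlations",
                    s, np.where(sd == 0)[0].tolist(),
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(block.T)
            c[np.diag_indices(G)] = np.where(sd > 0, 1.0, np.nan)
            mats.append(c)
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(np.stack(mats), axis=0)
        return CorrelationMatrix(values=avg, n_trials_used=amps.n_trials)
    if amps.n_trials < 3:
        raise ValueError("need at least 3 trials")
    c = np.corrcoef(amps.values.T)
    return CorrelationMatrix(values=c, n_trials_used=amps.n_trials, aggregation="per-stimulus")


def cluster_tuning(tuning: TuningMatrix, n_clusters: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage hierarchical clustering of mean tuning vectors.

    Euclidean distance on the glomeruli x stimuli tuning matrix; returns
    ``(labels, linkage_matrix)`` with labels from cutting the dendrogram at
    ``n_clusters`` groups.
    """
    if n_clusters > tuning.n_glomeruli:
        raise ValueError("n_clusters must not exceed the number of glomeruli")
    if not np.all(np.isfinite(tuning.values)):
        raise ValueError("tuning matrix contains non-finite values")
    Z = linkage(tuning.values, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def _mean_removed(amps: AmplitudeMatrix) -> np.ndarray:
    """Subtract the per-glomerulus, per-stimulus mean (noise residuals)."""
    resid = amps.values.astype(float).copy()
    for s in np.unique(amps.labels):
        sel = amps.labels == s
        resid[sel] -= resid[sel].mean(axis=0)
    return resid


def shared_gain(amps: AmplitudeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared trial-to-trial gain: PC1 of mean-removed amplitudes.

    Per-glomerulus, per-stimulus means are removed first so that the leading
    component captures trial-to-trial covariation rather than tuning
    differences.  The sign is oriented so the loading vector has positive
    mean (a larger score means a globally larger response, the gain
    convention).  Returns ``(score per trial, loadings, variance explained)``.
    """
    if amps.n_glomeruli < 2:
        raise ValueError("need at least 2 glomeruli")
    if amps.n_trials < 3:
        raise ValueError("need at least 3 trials")
    resid = _mean_removed(amps)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    loadings = vt[0]
    score = u[:, 0] * s[0]
    if loadings.mean() < 0:
        loadings = -loadings
        score = -score
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return score, loadings, var_explained


def behavior_correlation(amps: AmplitudeMatrix, behavior_amplitude: np.ndarray) -> np.ndarray:
    """Per-glomerulus Spearman correlation between amplitude and behavior.

    Amplitudes are mean-normalised within stimulus first (so the correlation
    reflects trial-to-trial gain rather than stimulus tuning); with a single
    stimulus this is a plain Spearman correlation.
    """
    behavior = np.asarray(behavior_amplitude, dtype=float)
    if len(behavior) != amps.n_trials:
        raise ValueError("behavior must be aligned per trial")
    if behavior.std() == 0:
        raise ValueError("constant behavior vector")
    resid = amps.values.astype(float).copy()
    for s in np.unique(amps.labels):
        sel = amps.labels == s
        mu = resid[sel].mean(axis=0)
        resid[sel] = resid[sel] / np.where(mu != 0, mu, 1.0)
    rho = np.array(
        [stats.spearmanr(resid[:, g], behavior).statistic for g in range(amps.n_glomeruli)]
    )
    return rho


def behavior_correlation_test(
    rho_per_fly: np.ndarray, alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """Across-fly test for negative behavior-gain coupling per glomerulus.

    One-sample, one-sided t-test of the per-fly Spearman rho against 0
    (alternative rho < 0), Holm step-down Bonferroni corrected at ``alpha``.
    ``rho_per_fly`` is flies x glomeruli.  Returns mean rho, raw and adjusted
    p-values, and the significance flags.
    """
    from statsmodels.stats.multitest import multipletests

    rho = np.atleast_2d(np.asarray(rho_per_fly, dtype=float))
    if rho.shape[0] < 2:
        raise ValueError("need rho from at least two flies for the t-test")
    t, p = stats.ttest_1samp(rho, 0.0, axis=0, alternative="less")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return {
        "mean_rho": rho.mean(axis=0),
        "t": t,
        "p": p,
        "p_holm": p_adj,
        "significant": reject,
    }


def shuffle_trials(amps: AmplitudeMatrix, seed: int | None = 0) -> AmplitudeMatrix:
    """Within-stimulus trial shuffle, independent per glomerulus.

    Exactly preserves each glomerulus's per-stimulus amplitude multiset (and
    hence means and variances) while destroying cross-glomerulus trial
    correlations in expectation.
    """
    rng = np.random.default_rng(seed)
    out = amps.values.copy()
    for s in np.unique(amps.labels):
        idx = np.where(amps.labels == s)[0]
        for g in range(amps.n_glomeruli):
            out[idx, g] = out[rng.permutation(idx), g]
    return replace(amps, values=out)


def decode(
    amps: AmplitudeMatrix,
    train_frac: float = 0.9,
    n_iterations: int = 100,
    seed: int | None = 0,
    C: float = 1.0,
    shuffled: bool = False,
) -> DecodingResult:
    """Multinomial logistic regression decoding of stimulus identity.

    Per iteration: a stratified ``train_frac`` / ``1 - train_frac`` split of
    trials, per-glomerulus z-scoring fit on the training split only, an
    L2-penalised multinomial logistic fit, and evaluation on the held-out
    trials.  Accuracies and the row-normalised confusion matrix are averaged
    over iterations; everything is deterministic given ``seed``.
    """
    classes, y = np.unique(amps.labels, return_inverse=True)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 stimulus classes")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")
    rng = np.random.default_rng(seed)
    X = amps.values
    confusion_counts = np.zeros((K, K))
    accs = np.empty(n_iterations)
    for it in range(n_iterations):
        test_idx = []
        for k in range(K):
            members = np.where(y == k)[0]
            n_test = max(1, int(round(len(members) * (1.0 - train_frac))))
            test_idx.append(rng.choice(members, size=n_test, replace=False))
        test_idx = np.concatenate(test_idx)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        mu = X[train_mask].mean(axis=0)
        sd = X[train_mask].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[train_mask] - mu) / sd
        Xte = (X[test_idx] - mu) / sd
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        model.fit(Xtr, y[train_mask])
        pred = model.predict(Xte)
        accs[it] = np.mean(pred == y[test_idx])
        np.add.at(confusion_counts, (y[test_idx], pred), 1)
    row_sums = confusion_counts.sum(axis=1, keepdims=True)
    confusion = confusion_counts / np.where(row_sums > 0, row_sums, 1.0)
    return DecodingResult(
        overall_accuracy=float(accs.mean()),
        per_class_accuracy=np.diag(confusion),
        confusion=confusion,
        classes=classes,
        n_iterations=n_iterations,
        shuffled=shuffled,
    )
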