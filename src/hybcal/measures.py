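"""Model-based and model-free protocol quality measures.

The information a calibration experiment carries about the compared samples is
quantified per gene by a pair of equivalent representations:

* a *generative* view — class-conditional Gaussians with shared standard
  deviation, N(x | mu_{g,y}, sigma_g), whose joint log-likelihood over all
  genes and observations scores a protocol on the intensity scale; and
* its *dual* — the posterior P(y=1 | x) is exactly a logistic function
  ``sigmoid(w x + b)`` with ``w = (mu1 - mu0) / sigma^2`` and
  ``b = (mu0^2 - mu1^2) / (2 sigma^2) + log(prior1 / (1 - prior1))``,
  i.e. a per-gene naive-Bayes classifier whose log-posterior sum scores the
  protocol on the label scale.

Model-free diagnostics (held-out classification accuracy, per-gene ROC curves
and the mutual-information bit rate) are computed by N-fold cross-testing in
which the folding unit is the slide, so the two channel-observations of one
slide are never split between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel_io import ExpressionSet, ValidationError

__all__ = [
    "GeneModel",
    "CrossTestResult",
    "ProtocolScore",
    "fit_gene_models",
    "loglik_linear",
    "nb_posterior",
    "loglik_nb",
    "cross_test",
    "generalization_accuracy",
    "roc_summary",
    "mutual_information",
    "score_protocol",
    "write_score_report",
]

SIGMA_FLOOR = 1e-6
POSTERIOR_EPS = 1e-6
LN2 = log(2.0)


@dataclass
class GeneModel:
    """Per-gene class-conditional Gaussian fit and its logistic dual.

    ``mu0``/``mu1`` are the class means on the (log) intensity scale,
    ``sigma`` the pooled maximum-likelihood standard deviation (floored at a
    small positive value) and ``prior1`` the training frequency of label 1.
    """

    gene_id: str
    mu0: float
    mu1: float
    sigma: float
    prior1: float

    @property
    def w(self) -> float:
        return (self.mu1 - self.mu0) / self.sigma**2

    @property
    def b(self) -> float:
        return (self.mu0**2 - self.mu1**2) / (2.0 * self.sigma**2) + log(
            self.prior1 / (1.0 - self.prior1)
        )

    def posterior(self, x, eps: float = POSTERIOR_EPS):
        """P(y=1 | x) via the logistic dual, clipped to [eps, 1-eps]."""
        p = expit(self.w * np.asarray(x, dtype=float) + self.b)
        return np.clip(p, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# Vectorized internals (array fast paths used by ranking and the simulators)
# ---------------------------------------------------------------------------

def fit_arrays(
    values: np.ndarray, y: np.ndarray, sigma_floor: float = SIGMA_FLOOR
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ML class means, pooled ML sigma (denominator N) and prior1, per gene row."""
    y = np.asarray(y)
    n = y.size
    m0 = y == 0
    m1 = ~m0
    if not (m0.any() and m1.any()):
        raise ValidationError("both sample labels must occur")
    mu0 = values[:, m0].mean(axis=1)
    mu1 = values[:, m1].mean(axis=1)
    ss = ((values[:, m0] - mu0[:, None]) ** 2).sum(axis=1)
    ss += ((values[:, m1] - mu1[:, None]) ** 2).sum(axis=1)
    sigma = np.maximum(np.sqrt(ss / n), sigma_floor)
    return mu0, mu1, sigma, float(m1.mean())


def posterior_arrays(
    values: np.ndarray,
    mu0: np.ndarray,
    mu1: np.ndarray,
    sigma: np.ndarray,
    prior1: float,
    eps: float = POSTERIOR_EPS,
) -> np.ndarray:
    """P(y=1 | x) for every (gene, observation) entry of ``values``."""
    w = (mu1 - mu0) / sigma**2
    b = (mu0**2 - mu1**2) / (2.0 * sigma**2) + log(prior1 / (1.0 - prior1))
    return np.clip(expit(w[:, None] * values + b[:, None]), eps, 1.0 - eps)


def loglik_nb_fit(
    values: np.ndarray,
    y: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
    eps: float = POSTERIOR_EPS,
) -> float:
    """Fit the per-gene models on (values, y) and return their naive-Bayes
    log-likelihood (sum of log posteriors at the observed labels) in nats."""
    mu0, mu1, sigma, prior1 = fit_arrays(values, y, sigma_floor)
    p1 = posterior_arrays(values, mu0, mu1, sigma, prior1, eps)
    p_obs = np.where(np.asarray(y) == 1, p1, 1.0 - p1)
    return float(np.log(p_obs).sum())


def _models_to_arrays(models: Sequence[GeneModel]):
    mu0 = np.array([m.mu0 for m in models])
    mu1 = np.array([m.mu1 for m in models])
    sigma = np.array([m.sigma for m in models])
    prior1 = float(models[0].prior1)
    return mu0, mu1, sigma, prior1


def _check_alignment(es: ExpressionSet, models: Sequence[GeneModel]) -> None:
    if len(models) != es.n_genes or any(
        m.gene_id != g for m, g in zip(models, es.gene_ids)
    ):
        raise ValidationError("models are not aligned with the gene ids of the data")


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def fit_gene_models(
    es: ExpressionSet,
    subset: Sequence[str] | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> list[GeneModel]:
    """Maximum-likelihood Gaussian models, one per gene (optionally a subset)."""
    data = es if subset is None else es.subset_genes(subset)
    mu0, mu1, sigma, prior1 = fit_arrays(data.values, data.y, sigma_floor)
    return [
        GeneModel(g, float(a), float(b), float(s), prior1)
        for g, a, b, s in zip(data.gene_ids, mu0, mu1, sigma)
    ]


def loglik_linear(es: ExpressionSet, models: Sequence[GeneModel]) -> float:
    """Joint Gaussian log-likelihood (nats): sum over genes and observations of
    ``ln N(x_{g,n}; mu_{g,y_n}, sigma_g)``."""
    _check_alignment(es, models)
    mu0, mu1, sigma, _ = _models_to_arrays(models)
    y = es.y
    mu = np.where(y[None, :] == 1, mu1[:, None], mu0[:, None])
    resid = es.values - mu
    n = es.n_obs
    ll = (
        -0.5 * es.n_genes * n * log(2.0 * np.pi)
        - n * np.log(sigma).sum()
        - float((resid**2 / (2.0 * sigma[:, None] ** 2)).sum())
    )
    return float(ll)


def nb_posterior(x, model: GeneModel, eps: float = POSTERIOR_EPS):
    """Posterior P(y=1 | x) of the naive-Bayes dual for a single gene model."""
    return model.posterior(x, eps=eps)


def loglik_nb(
    es: ExpressionSet, models: Sequence[GeneModel], eps: float = POSTERIOR_EPS
) -> float:
    """Naive-Bayes log-likelihood (nats): sum of log posteriors at the observed
    labels. The label-independent normalization constant is omitted, so the
    value is <= 0 and differences between protocols are unaffected."""
    _check_alignment(es, models)
    mu0, mu1, sigma, prior1 = _models_to_arrays(models)
    p1 = posterior_arrays(es.values, mu0, mu1, sigma, prior1, eps)
    p_obs = np.where(es.y[None, :] == 1, p1, 1.0 - p1)
    return float(np.log(p_obs).sum())


@dataclass
class CrossTestResult:
    """Held-out posteriors from N-fold cross-testing over slides.

    ``posteriors[g, n]`` is P(y=1 | x_{g,n}) estimated by the model trained
    with observation n's slide held out; ``priors[n]`` is the corresponding
    training-fold frequency of label 1.
    """

    gene_ids: list[str]
    posteriors: np.ndarray  # (G, N)
    y: np.ndarray  # (N,)
    priors: np.ndarray  # (N,)
    fold_of_slide: dict[str, int]

    @property
    def n_folds(self) -> int:
        return len(set(self.fold_of_slide.values()))


def cross_test(
    es: ExpressionSet,
    n_folds: int | str = "loo",
    sigma_floor: float = SIGMA_FLOOR,
    eps: float = POSTERIOR_EPS,
) -> CrossTestResult:
    """N-fold cross-testing with the slide as folding unit.

    Folds partition the slides (both channel-observations of a slide stay
    together, preventing within-slide leakage); ``"loo"`` uses one slide per
    fold. For each fold the models are refit on the remaining slides and the
    held-out observations receive test posteriors.
    """
    slides = es.slides
    if n_folds == "loo":
        folds = [[s] for s in slides]
    else:
        k = int(n_folds)
        if k < 1 or k > len(slides):
            raise ValidationError(
                f"n_folds must be in 1..{len(slides)}, got {n_folds}"
            )
        folds = [list(f) for f in np.array_split(np.array(slides, dtype=object), k)]
    slide_arr = es.obs["slide"].to_numpy()
    posteriors = np.empty_like(es.values)
    priors = np.empty(es.n_obs)
    fold_of_slide: dict[str, int] = {}
    for i, fold in enumerate(folds):
        test_mask = np.isin(slide_arr, fold)
        train_mask = ~test_mask
        if len(slides) - len(fold) < 2:
            raise ValidationError("each training set needs at least 2 slides")
        mu0, mu1, sigma, prior1 = fit_arrays(
            es.values[:, train_mask], es.y[train_mask], sigma_floor
        )
        posteriors[:, test_mask] = posterior_arrays(
            es.values[:, test_mask], mu0, mu1, sigma, prior1, eps
        )
        priors[test_mask] = prior1
        for s in fold:
            fold_of_slide[str(s)] = i
    return CrossTestResult(
        gene_ids=list(es.gene_ids),
        posteriors=posteriors,
        y=es.y.copy(),
        priors=priors,
        fold_of_slide=fold_of_slide,
    )


def generalization_accuracy(ct: CrossTestResult) -> float:
    """Percent of held-out label predictions that are correct, averaged over
    genes and test observations. A posterior of exactly 0.5 predicts label 0
    (deterministic tie rule), so ties count as incorrect for label-1
    observations and correct for label-0 observations."""
    pred1 = ct.posteriors > 0.5
    correct = pred1 == (ct.y[None, :] == 1)
    return float(100.0 * correct.mean())


def roc_summary(
    ct: CrossTestResult, grid_points: int = 101
) -> tuple[pd.DataFrame, float]:
    """Per-gene ROC analysis of the held-out posteriors.

    Each gene's ROC curve is computed from its own test posteriors by
    threshold enumeration and summarized by the trapezoidal AUC. The averaged
    curve interpolates every gene's TPR on a fixed FPR grid and averages
    vertically; ``mean_auc`` is the mean of the per-gene AUCs.
    """
    from sklearn.metrics import roc_curve

    y = ct.y
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present in test labels")
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = np.empty((len(ct.gene_ids), grid_points))
    aucs = np.empty(len(ct.gene_ids))
    for g in range(len(ct.gene_ids)):
        fpr, tpr, _ = roc_curve(y, ct.posteriors[g], drop_intermediate=False)
        tprs[g] = np.interp(grid, fpr, tpr)
        aucs[g] = np.trapezoid(tpr, fpr)
    curve = pd.DataFrame({"fpr": grid, "tpr": tprs.mean(axis=0)})
    return curve, float(aucs.mean())


def mutual_information(ct: CrossTestResult) -> float:
    """Average bit rate per gene: mean over genes of
    ``(1/N) * sum_n log2(P(y_n | x_{g,n}) / P(y_n))``.

    The finite-sample estimate may be slightly negative for uninformative
    genes (the held-out posterior is then a worse predictor than the prior);
    it is reported unclipped.
    """
    p_obs = np.where(ct.y[None, :] == 1, ct.posteriors, 1.0 - ct.posteriors)
    prior_obs = np.where(ct.y == 1, ct.priors, 1.0 - ct.priors)
    per_gene = (np.log(p_obs) - np.log(prior_obs)[None, :]).mean(axis=1) / LN2
    return float(per_gene.mean())


@dataclass
class ProtocolScore:
    """Joint quality measures for one protocol on one gene subset."""

    protocol: str
    loglik_linear: float  # nats, Gaussian representation
    loglik_nb: float  # nats, naive-Bayes (label) representation, <= 0
    accuracy_pct: float  # held-out generalization accuracy, percent
    mean_auc: float  # mean per-gene held-out AUC
    bitrate: float  # mutual information, bits per gene
    n_sig: int | None = None  # differentially expressed genes at the FDR cutoff
    subset: str = "all"

    def as_row(self) -> dict:
        return {
            "K": self.protocol,
            "acc": self.accuracy_pct,
            "I": self.bitrate,
            "logL_nb": self.loglik_nb,
            "logL_linear": self.loglik_linear,
            "mean_auc": self.mean_auc,
            "n_sig": self.n_sig if self.n_sig is not None else "",
            "subset": self.subset,
        }


def score_protocol(
    es_per_protocol: Mapping[str, ExpressionSet],
    subset: Sequence[str] | None = None,
    folds: int | str = "loo",
    sigma_floor: float = SIGMA_FLOOR,
    eps: float = POSTERIOR_EPS,
    fdr_cutoff: float | None = None,
    subset_name: str | None = None,
) -> list[ProtocolScore]:
    """Compute one :class:`ProtocolScore` per protocol on a shared gene subset.

    All expression sets must carry identical gene ids. When ``fdr_cutoff`` is
    given, the per-protocol differential-expression count ``n_sig`` is filled
    in as well.
    """
    if not es_per_protocol:
        raise ValidationError("at least one protocol is required")
    gene_sets = [tuple(es.gene_ids) for es in es_per_protocol.values()]
    if len(set(gene_sets)) != 1:
        raise ValidationError("gene ids differ across protocols")
    if subset is not None and len(list(subset)) == 0:
        raise ValidationError("empty gene subset")
    label = subset_name or ("all" if subset is None else f"subset[{len(list(subset))}]")
    scores = []
    for k, es in es_per_protocol.items():
        data = es if subset is None else es.subset_genes(subset)
        models = fit_gene_models(data, sigma_floor=sigma_floor)
        ct = cross_test(data, folds, sigma_floor=sigma_floor, eps=eps)
        _, mean_auc = roc_summary(ct)
        n_sig = None
        if fdr_cutoff is not None:
            from . import de_impact

            ratios = de_impact.dye_swap_log_ratios(data)
            de = de_impact.de_test(ratios, protocol=k)
            n_sig = de_impact.count_significant(de, fdr_cutoff)
        scores.append(
            ProtocolScore(
                protocol=k,
                loglik_linear=loglik_linear(data, models),
                loglik_nb=loglik_nb(data, models, eps=eps),
                accuracy_pct=generalization_accuracy(ct),
                mean_auc=mean_auc,
                bitrate=mutual_information(ct),
                n_sig=n_sig,
                subset=label,
            )
        )
    return scores


def write_score_report(scores: Sequence[ProtocolScore], path) -> None:
    """Write the protocol score table as TSV (one row per protocol)."""
    pd.DataFrame([s.as_row() for s in scores]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
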