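"""Single-gene staging classifier: split, logistic fit, ROC.

The protocol reserves roughly one quarter of a cohort to train a univariate
logistic regression on one gene's expression and evaluates it on the
remaining three quarters with a receiver-operating-characteristic curve.
Because a univariate logistic model is a monotone transform of its input,
the model's test AUC equals the AUC of the raw expression values; both are
reported so the equivalence is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import CohortMatrix
from .errors import (
    InvalidArgumentError,
    SeparationWarning,
    SplitError,
    UndefinedAUCError,
)


@dataclass
class SplitPlan:
    """A deterministic train/test partition of a cohort."""

    train_ids: List[str]
    test_ids: List[str]
    train_fraction: float
    seed: int
    stratified: bool


@dataclass
class LogisticFit:
    """Univariate logistic coefficients with fit diagnostics."""

    intercept: float
    slope: float
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    """ROC curve and area for one score vector."""

    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int
    model_coefficients: Optional[Tuple[float, float]] = None


def split_cohort(
    sample_ids: Sequence[str],
    labels: Sequence,
    train_fraction: float = 0.25,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Partition samples into train/test, deterministically for a seed.

    The train size is round(train_fraction * n).  Stratified splitting
    allocates per-class train counts by largest remainder, keeping each
    class's train share within one sample of ``train_fraction``.  A class
    absent from either side raises :class:`SplitError`.
    """
    ids = list(map(str, sample_ids))
    y = np.asarray(labels)
    if len(ids) != len(y):
        raise InvalidArgumentError("sample_ids and labels differ in length")
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate sample ids")
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    n = len(ids)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)

    if not stratified:
        order = rng.permutation(n)
        train_idx = set(order[:n_train].tolist())
    else:
        classes, counts = np.unique(y, return_counts=True)
        if (counts < 2).any():
            raise SplitError("stratified split needs >=2 samples per class")
        exact = counts * train_fraction
        base = np.floor(exact).astype(int)
        shortfall = n_train - base.sum()
        # hand remaining slots to the classes with the largest fractional parts
        order_rem = np.argsort(-(exact - base), kind="stable")
        for j in order_rem[: max(shortfall, 0)]:
            base[j] += 1
        train_idx = set()
        for cls, k in zip(classes, base):
            members = np.flatnonzero(y == cls)
            picked = rng.permutation(members)[:k]
            train_idx.update(picked.tolist())

    train_ids = [ids[i] for i in range(n) if i in train_idx]
    test_ids = [ids[i] for i in range(n) if i not in train_idx]
    for side, side_ids in (("train", train_ids), ("test", test_ids)):
        side_classes = set(y[[ids.index(i) for i in side_ids]])
        if side_classes != set(np.unique(y)):
            raise SplitError(f"class missing from {side} set")
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        train_fraction=train_fraction,
        seed=seed,
        stratified=stratified,
    )


def fit_univariate_logistic(
    x: Sequence[float],
    y: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(y=1|x) by IRLS.

    Iteration stops when the log-likelihood improves by less than ``tol``
    or after ``max_iter`` Newton steps.  Perfect separation is flagged via
    :class:`SeparationWarning` and the coefficients at the iteration cap
    are returned rather than diverging silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidArgumentError("x and y must be matching 1-d arrays")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise InvalidArgumentError("y must contain both classes, coded 0/1")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("x is constant; slope is unidentifiable")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    separation = False
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if ll - ll_old < tol and n_iter > 1:
            converged = True
            break
        ll_old = ll
        w = mu * (1 - mu)
        # Newton step: (X' W X)^-1 X' (y - mu)
        xtwx = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.abs(beta).max() > 1e4:
            separation = True
            break
    # diagnose separation: perfect classification with the likelihood driven
    # to (numerically) its supremum of 0 means the MLE is at infinity
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    if not separation:
        perfect = np.all((mu > 0.5) == (y == 1))
        ll_now = float(
            np.sum(y * np.log(np.clip(mu, 1e-12, None))
                   + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None)))
        )
        if perfect and ll_now > -1e-6:
            separation = True
    if separation:
        warnings.warn(
            "perfect separation detected; coefficients are unbounded MLEs "
            "reported at the iteration cap",
            SeparationWarning,
            stacklevel=2,
        )
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        converged=converged,
        separation=separation,
        n_iter=n_iter,
        log_likelihood=ll,
    )


def roc_auc(
    scores: Sequence[float],
    y: Sequence[int],
    model_coefficients: Optional[Tuple[float, float]] = None,
) -> RocResult:
    """ROC curve and trapezoidal AUC.

    The curve sweeps every distinct score as a threshold; ties contribute
    half credit, so the trapezoidal area equals the Mann-Whitney statistic
    (wins + 0.5 * ties) / (n_pos * n_neg).  A single-class ``y`` raises
    :class:`UndefinedAUCError`.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidArgumentError("scores and y must be matching 1-d arrays")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present to compute an AUC")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # one curve point per distinct threshold value
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        n_pos=n_pos,
        n_neg=n_neg,
        model_coefficients=model_coefficients,
    )


def classify_gene(
    cohort: CohortMatrix,
    gene: str,
    pos_stages: Sequence,
    neg_stages: Sequence,
    train_fraction: float = 0.25,
    seed: int = 0,
    stratified: bool = True,
) -> Dict:
    """Run the full staging protocol for one gene.

    Restricts the cohort to the two stage groups (positive = advanced),
    splits it, fits the univariate logistic model on the training quarter
    and evaluates ROC/AUC on the test three-quarters.  Both the model AUC
    and the raw-expression AUC are returned; they are equal whenever the
    fitted slope is positive because the model is monotone in x.
    """
    if gene not in cohort.gene_ids:
        raise InvalidArgumentError(f"gene {gene!r} not in cohort")
    stage = cohort.samples["stage"]
    pos_set, neg_set = set(pos_stages), set(neg_stages)
    mask = stage.isin(pos_set | neg_set)
    ids = list(cohort.sample_ids[mask])
    y = stage[mask].isin(pos_set).astype(int).to_numpy()
    x = np.log2(cohort.values.loc[gene, mask].to_numpy(dtype=float) + 1.0)

    plan = split_cohort(ids, y, train_fraction=train_fraction, seed=seed, stratified=stratified)
    pos = {i: j for j, i in enumerate(ids)}
    tr = [pos[i] for i in plan.train_ids]
    te = [pos[i] for i in plan.test_ids]
    fit = fit_univariate_logistic(x[tr], y[tr])
    model_scores = fit.predict_proba(x[te])
    roc_model = roc_auc(model_scores, y[te], model_coefficients=(fit.intercept, fit.slope))
    roc_raw = roc_auc(x[te], y[te])
    return {
        "gene": gene,
        "split": plan,
        "fit": fit,
        "roc_model": roc_model,
        "roc_raw": roc_raw,
        "auc": roc_model.auc,
        "n_train": len(tr),
        "n_test": len(te),
    }
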