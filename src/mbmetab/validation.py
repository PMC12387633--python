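"""Model quality metrics: R²Y, leave-one-out Q²Y, and multiclass AUROC.

R²Y is the fraction of (centered) response variance the fitted model
explains.  Q²Y is its cross-validated counterpart: every sample is left
out in turn, the *entire* chain — PQN reference, zero replacement, column
means and divisors, block divisors, and the MBPLS fit itself — is refit on
the remaining samples, and the held-out sample is predicted with the
frozen training parameters.  No statistic of a held-out sample ever enters
its training fold, so Q²Y may legitimately go negative on uninformative
data.

AUROC is computed one-vs-rest per class from the cross-validated predicted
Y columns with the rank (Mann–Whitney) formulation, ties receiving half
credit; the macro value is the unweighted mean over classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .blocks import BlockMatrix, ResponseMatrix, StudyDesign
from .mbpls import MBPLSModel, fit_mbpls
from .preprocessing import PreprocessParams, StudyPreprocessor


def r2y(Y, Y_hat) -> float:
    """1 − SS(Y − Ŷ) / SS(Y centered)."""
    Yv = Y.Y if isinstance(Y, ResponseMatrix) else np.asarray(Y, float)
    Yh = np.asarray(Y_hat, float)
    ss_tot = np.sum((Yv - Yv.mean(axis=0)) ** 2)
    if ss_tot == 0:
        raise ValueError("Y has zero variance")
    return float(1.0 - np.sum((Yv - Yh) ** 2) / ss_tot)


def auroc_binary(y_true: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUROC by the Mann–Whitney rank statistic (ties → 0.5)."""
    y_true = np.asarray(y_true, bool)
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y_true].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_multiclass(y_true, y_score: np.ndarray,
                     classes: list | None = None) -> dict:
    """Per-class one-vs-rest AUROC plus the unweighted macro mean.

    Parameters
    ----------
    y_true:
        Class labels per sample.
    y_score:
        (n x g) continuous scores; column j scores class ``classes[j]``.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, float)
    if classes is None:
        classes = sorted(set(y_true.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    per_class = {}
    for j, c in enumerate(classes):
        mask = y_true == c
        if not mask.any():
            raise ValueError(f"class {c!r} absent from y_true")
        per_class[c] = auroc_binary(mask, y_score[:, j])
    macro = float(np.mean(list(per_class.values())))
    return {"per_class": per_class, "macro": macro}


@dataclass
class ValidationReport:
    """R²Y, LOO Q²Y and AUROC of one (single- or multi-block) PLS model."""

    r2y: float
    q2y: float
    q2y_per_component: np.ndarray
    auroc_per_class: dict
    auroc_macro: float
    auroc_fitted_macro: float | None
    n_components: int
    cv_scheme: str = "leave-one-out"

    def to_dict(self) -> dict:
        return {"R2Y": self.r2y, "Q2Y": self.q2y,
                "Q2Y_per_component": np.asarray(self.q2y_per_component).tolist(),
                "AUROC_per_class": dict(self.auroc_per_class),
                "AUROC_macro": self.auroc_macro,
                "AUROC_fitted_macro": self.auroc_fitted_macro,
                "n_components": self.n_components,
                "cv_scheme": self.cv_scheme}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1)

    def format_table(self) -> str:
        rows = [("R2Y", f"{self.r2y:.4f}", "fit"),
                ("Q2Y", f"{self.q2y:.4f}", self.cv_scheme)]
        for c, v in self.auroc_per_class.items():
            rows.append((f"AUROC[{c}]", f"{v:.4f}", self.cv_scheme))
        rows.append(("AUROC[macro]", f"{self.auroc_macro:.4f}", self.cv_scheme))
        w = max(len(r[0]) for r in rows)
        lines = [f"{'metric':<{w}}  value   scheme",
                 "-" * (w + 22)]
        lines += [f"{m:<{w}}  {v:>6}  {s}" for m, v, s in rows]
        return "\n".join(lines)


@dataclass
class LOOResult:
    """Raw leave-one-out output: cumulative Q²Y per component count and the
    held-out predicted Y at each component count (n x g x A)."""

    q2y_per_component: np.ndarray
    predictions: np.ndarray
    fold_models: list = field(default_factory=list)
    fold_preprocessors: list = field(default_factory=list)

    @property
    def q2y(self) -> float:
        return float(self.q2y_per_component[-1])


def loo_q2y(blocks_raw: list[BlockMatrix], design: StudyDesign,
            params: PreprocessParams | None = None, n_components: int = 4,
            keep_models: bool = False) -> LOOResult:
    """Leave-one-out cross-validation with full preprocessing refit per fold.

    Requires n ≥ 3 and at least two samples per group so that no training
    fold loses a whole group.  Q²Y = 1 − PRESS / SS(Y centered by the
    training-fold means), reported cumulatively at 1..A components.
    """
    params = params or PreprocessParams()
    n = len(design.samples)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    Y = design.response_matrix()
    groups = Y.groups
    A = n_components
    g = len(groups)
    press = np.zeros(A)
    tss = 0.0
    preds = np.zeros((n, g, A))
    models: list = []
    preprocs: list = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        d_train = design.subset(train)
        if set(d_train.conditions) != set(design.conditions):
            raise ValueError(
                f"training fold without sample {design.samples[i]} loses a "
                f"whole group; need >= 2 samples per group")
        pre, tblocks = StudyPreprocessor.fit(
            [b.subset_samples(train) for b in blocks_raw], params)
        test = pre.apply([b.subset_samples(np.array([i])) for b in blocks_raw])
        # keep the global group order regardless of fold sample order
        Ytr = ResponseMatrix(
            np.column_stack([(np.asarray(d_train.conditions) == c).astype(float)
                             for c in groups]), list(groups))
        model = fit_mbpls(tblocks, Ytr, A)
        for a in range(1, A + 1):
            yhat = model.predict(test, n_components=a)[0]
            preds[i, :, a - 1] = yhat
            press[a - 1] += np.sum((Y.Y[i] - yhat) ** 2)
        tss += np.sum((Y.Y[i] - Ytr.Y.mean(axis=0)) ** 2)
        if keep_models:
            models.append(model)
            preprocs.append(pre)
    q2 = 1.0 - press / tss
    return LOOResult(q2y_per_component=q2, predictions=preds,
                     fold_models=models, fold_preprocessors=preprocs)


def evaluate(blocks_raw: list[BlockMatrix], design: StudyDesign,
             params: PreprocessParams | None = None, n_components: int = 4
             ) -> ValidationReport:
    """Assemble R²Y, LOO Q²Y and AUROC into one report.

    Works identically for a single block (plain PLS, to which MBPLS
    reduces) and for the full multiblock study.  AUROC uses the LOO
    held-out predicted Y columns; the optimistic fitted-score AUROC is
    reported alongside for comparison.
    """
    params = params or PreprocessParams()
    Y = design.response_matrix()
    _, fitted_blocks = StudyPreprocessor.fit(blocks_raw, params)
    model = fit_mbpls(fitted_blocks, Y, n_components)
    loo = loo_q2y(blocks_raw, design, params, n_components)
    y_labels = np.asarray(design.conditions)
    au_cv = auroc_multiclass(y_labels, loo.predictions[:, :, -1],
                             classes=Y.groups)
    au_fit = auroc_multiclass(y_labels, model.fitted_y, classes=Y.groups)
    return ValidationReport(
        r2y=model.r2y, q2y=loo.q2y,
        q2y_per_component=loo.q2y_per_component,
        auroc_per_class=au_cv["per_class"], auroc_macro=au_cv["macro"],
        auroc_fitted_macro=au_fit["macro"], n_components=n_components)
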