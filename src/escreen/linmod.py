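"""Stepwise multivariate activity classifier ("linmod").

Predicts a dichotomized output assay from potency scores of other assays.
Candidate columns are ranked by the significance of their univariate
association with the output (Welch t-test on -log10 AC50 scores); the model
score of a chemical is the signed sum of its scores over the first Nmax
ranked columns minus a Cutoff, and the chemical is predicted active iff the
score is strictly positive:

    score_c = sum_{i <= Nmax} sign_i * x_ci - Cutoff,   active <=> score_c > 0

where sign_i is the direction (+/-1) of column i's univariate association.
Nmax and Cutoff are tuned by stratified k-fold cross-validation (k = 5
realizes the 80%/20% train/test split): Nmax maximizes the mean held-out
ROC AUC, and Cutoff maximizes the balanced accuracy of the >0 decision rule
(the additive Cutoff cannot move the AUC, so AUC alone cannot identify it).
Ties prefer smaller Nmax, then smaller Cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .assoc import ttest_association


class UndefinedAUCError(ValueError):
    pass


class ContractError(KeyError):
    pass


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC and the >0-rule operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def points(self):
        return list(zip(self.fpr, self.tpr))


def roc_curve(scores, labels) -> RocResult:
    """Threshold-sweep ROC with trapezoid AUC.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counted half. The reported operating point is the
    score > 0 decision rule. Raises UndefinedAUCError if a class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedAUCError("both classes must be present")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    pred = scores > 0
    pos, neg = labels == 1, labels == 0
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[neg]))
    return RocResult(fpr, tpr, auc, sens, spec)


def _binary_metrics(scores, labels, cutoff):
    """sensitivity/specificity/BA/Fisher p of the score - cutoff > 0 rule."""
    pred = np.asarray(scores, float) - cutoff > 0
    labels = np.asarray(labels).astype(bool)
    sens = float(np.mean(pred[labels])) if labels.any() else np.nan
    spec = float(np.mean(~pred[~labels])) if (~labels).any() else np.nan
    table = [[int(np.sum(pred & labels)), int(np.sum(pred & ~labels))],
             [int(np.sum(~pred & labels)), int(np.sum(~pred & ~labels))]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return sens, spec, 0.5 * (sens + spec), float(fisher_p)


# ---------------------------------------------------------------------------
# Feature ranking and scoring


@dataclass(frozen=True)
class RankedFeature:
    column: str
    sign: int  # +1: higher scores among output-positives
    statistic: float
    p_value: float


def rank_features(scores: pd.DataFrame, output) -> list[RankedFeature]:
    """Columns ordered by ascending univariate p (Welch t on scores).

    Ties break by descending |t| and then by column id, so identical
    columns always rank deterministically. Untestable columns (a group
    smaller than 2, or no variance anywhere) are dropped.
    """
    y = np.asarray(output).astype(int)
    feats = []
    for col in scores.columns:
        r = ttest_association(scores[col].to_numpy(), y, input_col=col)
        if not r.testable or r.direction == 0:
            continue
        feats.append(RankedFeature(col, r.direction, float(r.statistic), float(r.p_value)))
    feats.sort(key=lambda f: (f.p_value, -abs(f.statistic), f.column))
    return feats


def _signed_sum(scores: pd.DataFrame, features: list[RankedFeature]) -> np.ndarray:
    total = np.zeros(len(scores))
    for f in features:
        if f.column not in scores.columns:
            raise ContractError(f"score vector lacks column {f.column!r}")
        total += f.sign * scores[f.column].to_numpy(float)
    return total


def _cutoff_grid(sums: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique score sums plus extremes."""
    u = np.unique(sums)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def _best_cutoff(sums, labels) -> float:
    """Grid cutoff maximizing balanced accuracy; ties to the smaller cutoff."""
    best = (-np.inf, np.inf)
    for cut in _cutoff_grid(np.asarray(sums, float)):
        _, _, ba, _ = _binary_metrics(sums, labels, cut)
        if ba > best[0] + 1e-12:
            best = (ba, cut)
    return float(best[1])


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class LinModResults:
    """Fitted linmod classifier with cross-validation diagnostics.

    ``included`` preserves inclusion order (univariate rank on the full
    data); ``cv_metrics`` holds one row per fold evaluated at the selected
    Nmax with the fold's training-data cutoff; ``cv_auc`` is the mean
    held-out AUC that selected Nmax.
    """

    output_name: str
    included: list[RankedFeature]
    nmax: int
    cutoff: float
    cv_auc: float
    cv_metrics: pd.DataFrame
    k_folds: int
    seed: int
    train_metrics: tuple = ()

    @property
    def included_cols(self) -> list[str]:
        return [f.column for f in self.included]

    @property
    def weights(self) -> dict:
        return {f.column: f.sign for f in self.included}

    def decision_scores(self, scores: pd.DataFrame) -> np.ndarray:
        """Signed score sum minus Cutoff for each chemical (row)."""
        return _signed_sum(scores, self.included) - self.cutoff

    def predict(self, scores: pd.DataFrame) -> np.ndarray:
        """Predicted activity: strictly positive decision score."""
        return self.decision_scores(scores) > 0

    def score_one(self, x) -> float:
        """Decision score for a single chemical's score vector (Series/dict)."""
        row = pd.DataFrame([pd.Series(x)])
        return float(self.decision_scores(row)[0])

    def summary(self) -> str:
        lines = [
            f"linmod classifier for output {self.output_name!r}",
            "=" * 54,
            f"{'Nmax':<26}{self.nmax:>12d}",
            f"{'Cutoff':<26}{self.cutoff:>12.4f}",
            f"{'CV folds':<26}{self.k_folds:>12d}",
            f"{'mean held-out AUC':<26}{self.cv_auc:>12.4f}",
            f"{'mean held-out BA':<26}{self.cv_metrics['balanced_accuracy'].mean():>12.4f}",
            "",
            f"{'rank':<6}{'column':<28}{'sign':>5}{'t':>10}{'p':>12}",
            "-" * 61,
        ]
        for i, f in enumerate(self.included, 1):
            lines.append(f"{i:<6}{f.column:<28}{f.sign:>+5d}{f.statistic:>10.3f}{f.p_value:>12.3g}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "output": self.output_name,
            "included_cols": self.included_cols,
            "signs": self.weights,
            "nmax": self.nmax,
            "cutoff": self.cutoff,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "cv_auc": self.cv_auc,
            "cv_metrics": self.cv_metrics.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class LinMod:
    """Stepwise signed-sum classifier over assay potency scores.

    Parameters
    ----------
    scores
        Chemicals x columns potency-score matrix (``AssayMatrix.scale_scores``).
    output
        Binary output vector aligned with the score rows.
    output_name
        Label carried into results/serialization.
    nmax_cap
        Largest Nmax searched; defaults to min(20, testable columns).
    """

    def __init__(self, scores: pd.DataFrame, output, output_name: str = "output",
                 nmax_cap: int | None = None):
        self.scores = scores
        self.output = np.asarray(output).astype(int)
        if len(self.output) != len(scores):
            raise ContractError("output length does not match score rows")
        self.output_name = output_name
        self.nmax_cap = nmax_cap

    def fit(self, k_folds: int = 5, seed: int = 0) -> LinModResults:
        y = self.output
        n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
        if len(y) < 2 * k_folds:
            raise UndefinedAUCError(f"need >= {2 * k_folds} chemicals for {k_folds}-fold CV")
        for label, count in (("positive", n_pos), ("negative", n_neg)):
            if count < k_folds:
                raise UndefinedAUCError(
                    f"{label} class has {count} members; needs >= {k_folds} to stratify"
                )
        cap = min(self.nmax_cap or 20, self.scores.shape[1])

        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(self.scores, y))
        fold_auc = np.full((k_folds, cap), np.nan)
        fold_data = []
        for i, (tr, te) in enumerate(folds):
            ranking = rank_features(self.scores.iloc[tr], y[tr])
            fold_data.append((tr, te, ranking))
            for nmax in range(1, min(cap, len(ranking)) + 1):
                s_te = _signed_sum(self.scores.iloc[te], ranking[:nmax])
                fold_auc[i, nmax - 1] = roc_curve(s_te, y[te]).auc

        have = np.sum(~np.isnan(fold_auc), axis=0)
        mean_auc = np.full(cap, -np.inf)
        np.divide(np.nansum(fold_auc, axis=0), have, out=mean_auc, where=have > 0)
        if not np.any(have > 0):
            raise UndefinedAUCError("no testable columns in any training fold")
        best_nmax = int(np.argmax(np.round(mean_auc, 12))) + 1

        rows = []
        for i, (tr, te, ranking) in enumerate(fold_data):
            feats = ranking[:best_nmax]
            if not feats:
                continue
            s_tr = _signed_sum(self.scores.iloc[tr], feats)
            s_te = _signed_sum(self.scores.iloc[te], feats)
            cut = _best_cutoff(s_tr, y[tr])
            sens, spec, ba, fisher_p = _binary_metrics(s_te, y[te], cut)
            rows.append((i, fold_auc[i, best_nmax - 1], sens, spec, ba, fisher_p, cut))
        cv_metrics = pd.DataFrame(
            rows, columns=["fold", "auc", "sensitivity", "specificity",
                           "balanced_accuracy", "fisher_p", "cutoff"],
        )

        full_ranking = rank_features(self.scores, y)
        included = full_ranking[:best_nmax]
        s_full = _signed_sum(self.scores, included)
        cutoff = _best_cutoff(s_full, y)
        train_metrics = _binary_metrics(s_full, y, cutoff)

        return LinModResults(
            self.output_name, included, best_nmax, cutoff,
            float(np.nanmean(fold_auc[:, best_nmax - 1])), cv_metrics,
            k_folds, seed, train_metrics,
        )


def fit_linmod(scores: pd.DataFrame, output, k_folds: int = 5, seed: int = 0,
               output_name: str = "output", nmax_cap: int | None = None) -> LinModResults:
    """Convenience wrapper: build and fit a LinMod in one call."""
    return LinMod(scores, output, output_name=output_name, nmax_cap=nmax_cap).fit(
        k_folds=k_folds, seed=seed
    )
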