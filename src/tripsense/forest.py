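"""Random-forest transport-mode models and evaluation regimes.

Models are bagged ensembles of 100 Gini-criterion decision trees with
library-default feature subsetting; the final prediction of a minute is
the class voted for by the largest number of trees. Two corrections to
the naive workflow are implemented:

* prevalence-weighted vote cut-offs — the per-class vote share is
  divided by the class's training prevalence before the argmax, so rare
  transport modes are not systematically out-voted by the dominant
  activity-place class (applied at forest aggregation, not inside tree
  growing);
* participant-level validation — leave-one-participant-out
  cross-validation (LOOCV) holds out every minute of one participant,
  while the "naive" out-of-bag (OOB) rate evaluates each training
  minute with the trees whose bootstrap excluded it. Because the naive
  split works at the minute level, minutes from the same participant
  appear on both sides, and participant-level sensor idiosyncrasies
  inflate the apparent transport prediction rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import MODES
from .evaluate import RatesReport, prediction_rates
from .features import FeatureCatalogue, default_catalogue

logger = logging.getLogger(__name__)


class TrainingError(ValueError):
    """Raised when a model cannot be trained or applied."""


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed to apply it."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    feature_set: str
    classes: tuple[str, ...]          # labels present, in fixed MODES order
    prevalence: np.ndarray            # training-class prevalence, sums to 1
    n_rows: int
    n_dropped: int                    # rows excluded for missing features

    @property
    def n_trees(self) -> int:
        return self.estimator.n_estimators


def _prepare_matrix(records: pd.DataFrame, feature_names: list[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    X = records[feature_names].to_numpy(dtype=np.float32)
    ok = ~np.isnan(X).any(axis=1)
    return X, ok


def train_forest(records: pd.DataFrame, feature_set: str = "with_hr",
                 n_trees: int = 100, seed: int = 0,
                 catalogue: FeatureCatalogue | None = None) -> ForestModel:
    """Fit a bagged forest on labelled minute records.

    Rows with any missing feature are excluded (and counted). The label
    column is ``label``; features come from the catalogue's feature set.
    Deterministic under a fixed seed.
    """
    catalogue = catalogue or default_catalogue()
    names = catalogue.feature_set(feature_set)
    X, ok = _prepare_matrix(records, names)
    y_lab = records["label"].to_numpy()
    X, y_lab = X[ok], y_lab[ok]
    n_dropped = int((~ok).sum())

    classes = tuple(m for m in MODES if m in set(y_lab))
    if len(classes) < 2:
        raise TrainingError(
            f"training data must contain >= 2 classes, got {classes}")
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code[v] for v in y_lab], dtype=np.int64)

    est = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", bootstrap=True,
        random_state=int(seed) % (2 ** 31), n_jobs=1)
    est.fit(X, y)
    prevalence = np.bincount(y, minlength=len(classes)) / y.size
    return ForestModel(estimator=est, feature_names=names,
                       feature_set=feature_set, classes=classes,
                       prevalence=prevalence, n_rows=int(y.size),
                       n_dropped=n_dropped)


def tree_vote_shares(model: ForestModel, records: pd.DataFrame) -> np.ndarray:
    """Per-minute fraction of trees voting for each class.

    Each tree casts one hard vote (its own predicted class); rows sum
    to 1. Rows with missing features get all-NaN shares.
    """
    X, ok = _prepare_matrix(records, model.feature_names)
    k = len(model.classes)
    shares = np.full((len(records), k), np.nan)
    if ok.any():
        Xv = X[ok]
        counts = np.zeros((Xv.shape[0], k))
        for est in model.estimator.estimators_:
            pred = est.predict(Xv).astype(np.int64)
            counts[np.arange(Xv.shape[0]), pred] += 1
        shares[ok] = counts / model.n_trees
    return shares


def oob_vote_shares(model: ForestModel, records: pd.DataFrame
                    ) -> tuple[np.ndarray, np.ndarray]:
    """OOB vote shares for the model's own training records.

    Each record is voted on only by trees whose bootstrap sample
    excluded it. Returns (shares, has_vote); records with no OOB tree
    (possible in tiny forests) have has_vote False and NaN shares.
    ``records`` must be the same frame the model was trained on.
    """
    X, ok = _prepare_matrix(records, model.feature_names)
    Xv = X[ok]
    n = Xv.shape[0]
    if n != model.n_rows:
        raise TrainingError(
            "oob_vote_shares must receive the model's training records")
    k = len(model.classes)
    counts = np.zeros((n, k))
    n_votes = np.zeros(n)
    for est, samples in zip(model.estimator.estimators_,
                            model.estimator.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        if not oob.any():
            continue
        pred = est.predict(Xv[oob]).astype(np.int64)
        counts[np.flatnonzero(oob), pred] += 1
        n_votes[oob] += 1

    shares_v = np.full((n, k), np.nan)
    voted = n_votes > 0
    shares_v[voted] = counts[voted] / n_votes[voted, None]

    shares = np.full((len(records), k), np.nan)
    has_vote = np.zeros(len(records), dtype=bool)
    shares[ok] = shares_v
    has_vote[ok] = voted
    return shares, has_vote


def classify_votes(shares: np.ndarray, classes: tuple[str, ...],
                   prevalence: np.ndarray | None = None) -> np.ndarray:
    """Predicted class per row from vote shares.

    Unweighted (prevalence None): plain argmax of shares. Weighted:
    argmax of share / prevalence, i.e. the prediction cut-off of each
    class is moved to its observed prevalence, so a rare class wins as
    soon as its vote share exceeds prevalence-proportional expectation.
    Ties break toward the earlier class in the fixed class order. Rows
    with NaN shares yield None.
    """
    shares = np.asarray(shares, dtype=float)
    if shares.ndim == 1:
        shares = shares[None, :]
    if prevalence is not None:
        prevalence = np.asarray(prevalence, dtype=float)
        if prevalence.shape != (shares.shape[1],):
            raise TrainingError("prevalence length must match class count")
        if np.any(prevalence <= 0):
            raise TrainingError(
                "all class prevalences must be > 0 for weighted cut-offs")
        scores = shares / prevalence
    else:
        scores = shares
    out = np.empty(scores.shape[0], dtype=object)
    ok = ~np.isnan(scores).any(axis=1)
    idx = np.argmax(scores[ok], axis=1)      # first max wins -> fixed order
    out[ok] = np.asarray(classes, dtype=object)[idx]
    out[~ok] = None
    return out


def weighted_classify(shares: np.ndarray, prevalence: np.ndarray,
                      classes: tuple[str, ...] = MODES) -> np.ndarray:
    """Prevalence-corrected classification of vote shares."""
    return classify_votes(shares, classes, prevalence=prevalence)


def naive_oob_rates(records: pd.DataFrame, feature_set: str = "with_hr",
                    n_trees: int = 100, seed: int = 0,
                    catalogue: FeatureCatalogue | None = None,
                    ) -> dict[str, RatesReport]:
    """Minute-level-split ("naive") OOB prediction rates.

    Trains a forest on all records and evaluates each record with its
    OOB trees only; reported both unweighted and with the prevalence
    cut-off correction. Records without an OOB vote are excluded.
    """
    model = train_forest(records, feature_set, n_trees, seed, catalogue)
    shares, has_vote = oob_vote_shares(model, records)
    truth = records["label"].to_numpy()[has_vote]
    sh = shares[has_vote]
    return {
        "unweighted": prediction_rates(
            truth, classify_votes(sh, model.classes)),
        "weighted": prediction_rates(
            truth, classify_votes(sh, model.classes, model.prevalence)),
    }


@dataclass
class FitResult:
    """One LOOCV iteration x feature set."""

    participant_id: str
    feature_set: str
    model: ForestModel | None
    model_classes: tuple[str, ...]
    prevalence: np.ndarray
    test_minutes: np.ndarray
    test_truth: np.ndarray
    test_shares: np.ndarray
    test_pred_unweighted: np.ndarray
    test_pred_weighted: np.ndarray
    test_rates_unweighted: RatesReport
    test_rates_weighted: RatesReport
    oob_rates_unweighted: RatesReport | None = None
    oob_rates_weighted: RatesReport | None = None


@dataclass
class LoocvResult:
    iterations: list[dict[str, FitResult]] = field(default_factory=list)

    def fits(self, feature_set: str) -> list[FitResult]:
        return [it[feature_set] for it in self.iterations if feature_set in it]


def loocv_run(records: pd.DataFrame,
              feature_sets: tuple[str, ...] = ("without_hr", "with_hr"),
              n_trees: int = 100, seed: int = 0, compute_oob: bool = True,
              catalogue: FeatureCatalogue | None = None,
              keep_models: bool = False) -> LoocvResult:
    """Leave-one-participant-out cross-validation.

    One iteration per participant: a forest per feature set is trained
    on all other participants' minutes and applied to the held-out
    participant. Optionally the naive OOB rates within each training
    set are computed for the split-bias comparison. Per-iteration seeds
    are derived from the master seed by fixed offsets.
    """
    catalogue = catalogue or default_catalogue()
    pids = list(pd.unique(records["participant_id"]))
    if len(pids) < 2:
        raise TrainingError("LOOCV needs >= 2 participants")
    result = LoocvResult()
    for i, pid in enumerate(pids):
        test = records[records["participant_id"] == pid]
        train = records[records["participant_id"] != pid]
        if len(test) == 0:
            logger.warning("participant %s has no merged minutes; skipping",
                           pid)
            continue
        iteration: dict[str, FitResult] = {}
        for j, fset in enumerate(feature_sets):
            it_seed = (int(seed) * 100_003 + i * 613 + j * 7) % (2 ** 31)
            model = train_forest(train, fset, n_trees, it_seed, catalogue)
            shares = tree_vote_shares(model, test)
            ok = ~np.isnan(shares).any(axis=1)
            truth = test["label"].to_numpy()[ok]
            sh = shares[ok]
            pred_u = classify_votes(sh, model.classes)
            pred_w = classify_votes(sh, model.classes, model.prevalence)
            fit = FitResult(
                participant_id=pid, feature_set=fset, model=model,
                model_classes=model.classes, prevalence=model.prevalence,
                test_minutes=test["minute"].to_numpy()[ok],
                test_truth=truth, test_shares=sh,
                test_pred_unweighted=pred_u, test_pred_weighted=pred_w,
                test_rates_unweighted=prediction_rates(truth, pred_u),
                test_rates_weighted=prediction_rates(truth, pred_w),
            )
            if compute_oob:
                oshares, ovote = oob_vote_shares(model, train)
                otruth = train["label"].to_numpy()[ovote]
                osh = oshares[ovote]
                fit.oob_rates_unweighted = prediction_rates(
                    otruth, classify_votes(osh, model.classes))
                fit.oob_rates_weighted = prediction_rates(
                    otruth, classify_votes(osh, model.classes,
                                           model.prevalence))
            if not keep_models:
                fit.model = None  # free tree memory in long runs
            iteration[fset] = fit
            logger.info("LOOCV %d/%d (%s, %s): overall %.1f%%",
                        i + 1, len(pids), pid, fset,
                        fit.test_rates_unweighted.overall
                        if fit.test_rates_unweighted.overall is not None
                        else float("nan"))
        result.iterations.append(iteration)
    return result


def bootstrap_inclusion_fraction(n: int, reps: int = 200,
                                 rng: np.random.Generator | int | None = None,
                                 ) -> tuple[float, float]:
    """Mean fractions of distinct originals in-bag and out-of-bag.

    Draws ``reps`` bootstrap resamples of size n with replacement and
    averages the fraction of distinct original indices included; the
    complement is the OOB fraction. Both converge to 1 - 1/e ~ 0.632
    and 1/e ~ 0.368 as n grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fracs = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, n)
        fracs[r] = np.unique(idx).size / n
    inbag = float(fracs.mean())
    return inbag, 1.0 - inbag


def variable_importance(model: ForestModel, records: pd.DataFrame
                        ) -> pd.DataFrame:
    """Per-feature importance: mean decrease in accuracy and in Gini.

    Accuracy decrease is permutation-based on OOB data, tree by tree:
    for each tree, its OOB rows are predicted with the feature column
    permuted and the drop in accuracy relative to unpermuted OOB
    predictions is averaged over trees. Gini importance is the mean
    decrease in node impurity accumulated during growing.
    ``records`` must be the model's training records.
    """
    X, ok = _prepare_matrix(records, model.feature_names)
    Xv = X[ok]
    if Xv.shape[0] != model.n_rows:
        raise TrainingError(
            "variable_importance must receive the model's training records")
    code = {c: i for i, c in enumerate(model.classes)}
    y = np.array([code[v] for v in records["label"].to_numpy()[ok]])
    p = len(model.feature_names)
    drops = np.zeros(p)
    n_used = np.zeros(p)
    rng = np.random.default_rng(model.estimator.random_state)
    for est, samples in zip(model.estimator.estimators_,
                            model.estimator.estimators_samples_):
        oob = np.ones(Xv.shape[0], dtype=bool)
        oob[samples] = False
        if not oob.any():
            continue
        Xo, yo = Xv[oob], y[oob]
        base = (est.predict(Xo).astype(np.int64) == yo).mean()
        # Permute only features the tree actually split on: others
        # cannot change its predictions.
        used = np.unique(est.tree_.feature)
        used = used[used >= 0]
        for jf in used:
            Xp = Xo.copy()
            Xp[:, jf] = Xp[rng.permutation(Xo.shape[0]), jf]
            perm = (est.predict(Xp).astype(np.int64) == yo).mean()
            drops[jf] += base - perm
            n_used[jf] += 1
        n_used[np.setdiff1d(np.arange(p), used)] += 1  # drop contribution 0
    mda = drops / np.maximum(n_used, 1)
    return pd.DataFrame({
        "feature": model.feature_names,
        "mean_decrease_accuracy": mda,
        "mean_decrease_gini": model.estimator.feature_importances_,
    }).sort_values("mean_decrease_accuracy", ascending=False,
                   ignore_index=True)
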