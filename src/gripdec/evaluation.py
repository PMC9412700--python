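"""Cross-validation regimes, decoding accuracy and chance-level estimation.

Three regimes probe different generalization questions:

* leave-one-run-out (LORO): within-subject — train on four of a subject's
  runs, test on the fifth;
* leave-one-subject-out (LOSO): across-subject — test on a participant the
  classifier has never seen;
* two-fold: train on half the participants and test on the other half, the
  halves formed either matched on age group and hand size, split by hand
  size (smallest vs largest), or split by age group.

Decoding accuracy (DA) is the percentage of test trials whose predicted
movement class is correct; per-class sensitivity is the per-task recall.
The empirical chance level comes from a permutation test: labels are
randomly reassigned to trials, the full cross-validation is rerun, and the
DA distribution over many permutations yields a 95% percentile confidence
interval whose upper bound serves as the significance threshold.  Template
selection and warping are label-independent, so the per-fold aligned
features are computed once and shared across permutations; this is exactly
equivalent to rerunning the whole pipeline per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dtw, svm
from .data import TASKS, Dataset, Trial
from .lstm import BiLstmClassifier, LstmArchitecture, TrainingParams
from .lstm import train as lstm_train

SCHEMES = ("leave_one_run_out", "leave_one_subject_out", "two_fold")
SPLIT_RULES = ("matched", "hand_size_grouped", "age_grouped")
CLASSIFIERS = ("svm_dtw", "lstm", "lstm_dtw")


@dataclass
class CVSpec:
    """Which cross-validation regime to run, with which decoder."""

    scheme: str = "leave_one_subject_out"
    classifier: str = "svm_dtw"
    split_rule: str = "matched"          # only used by two_fold
    lstm_arch: LstmArchitecture | None = None
    lstm_params: TrainingParams | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.split_rule not in SPLIT_RULES:
            raise ValueError(f"unknown split rule {self.split_rule!r}")


@dataclass
class Fold:
    name: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    subject_id: str | None = None   # owning subject for within-subject folds


@dataclass
class CVResult:
    """Pooled predictions and summary metrics of one cross-validation."""

    classes: list[str]
    true: np.ndarray
    pred: np.ndarray
    test_subjects: np.ndarray
    templates: list[dtw.Template] = field(default_factory=list)

    @property
    def da(self) -> float:
        """Decoding accuracy in percent."""
        return float(100.0 * np.mean(self.pred == self.true))

    @property
    def confusion(self) -> np.ndarray:
        """Rows = true class, columns = predicted class, counts."""
        k = len(self.classes)
        idx = {c: i for i, c in enumerate(self.classes)}
        cm = np.zeros((k, k), dtype=int)
        for t, p in zip(self.true, self.pred):
            cm[idx[t], idx[p]] += 1
        return cm

    @property
    def sensitivities(self) -> dict[str, float]:
        """Per-class recall in percent (diagonal over row sum)."""
        cm = self.confusion
        out = {}
        for i, c in enumerate(self.classes):
            rs = cm[i].sum()
            out[c] = float(100.0 * cm[i, i] / rs) if rs else float("nan")
        return out

    def per_subject_da(self) -> dict[str, float]:
        out = {}
        for s in np.unique(self.test_subjects):
            m = self.test_subjects == s
            out[s] = float(100.0 * np.mean(self.pred[m] == self.true[m]))
        return out

    @property
    def se(self) -> float:
        """Standard error of DA across subjects."""
        das = np.array(list(self.per_subject_da().values()))
        if len(das) < 2:
            return float("nan")
        return float(das.std(ddof=1) / np.sqrt(len(das)))


@dataclass
class PermutationResult:
    """DA distribution under random label reassignment."""

    das: np.ndarray                  # percent, one per permutation
    ci: tuple[float, float]          # 2.5th / 97.5th percentile

    @property
    def mean(self) -> float:
        return float(self.das.mean())

    @property
    def threshold(self) -> float:
        """Upper 95% CI bound: DAs above it are significant."""
        return self.ci[1]


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def _matched_split(dataset: Dataset) -> tuple[set[str], set[str]]:
    """Pair subjects by (age group, hand-size rank) and alternate assignment,
    so both folds match in age composition and hand-size distribution."""
    a: set[str] = set()
    b: set[str] = set()
    for group in ("young", "old"):
        ids = [s for s in dataset.subject_ids
               if dataset.subjects[s].age_group == group]
        ids.sort(key=lambda s: (dataset.subjects[s].hand_size, s))
        for i, s in enumerate(ids):
            (a if i % 2 == 0 else b).add(s)
    return a, b


def make_folds(dataset: Dataset, spec: CVSpec) -> list[Fold]:
    """Build the train/test index partition for the requested scheme."""
    subjects = np.array([t.subject_id for t in dataset.trials])
    runs = np.array([t.run for t in dataset.trials])
    all_idx = np.arange(dataset.n_trials)
    folds: list[Fold] = []
    if spec.scheme == "leave_one_run_out":
        for s in dataset.subject_ids:
            s_mask = subjects == s
            for r in sorted(set(runs[s_mask].tolist())):
                test = all_idx[s_mask & (runs == r)]
                train = all_idx[s_mask & (runs != r)]
                if len(train) == 0:
                    raise ValueError(f"subject {s}: only one run, LORO impossible")
                folds.append(Fold(f"{s}/run{r}", train, test, subject_id=s))
    elif spec.scheme == "leave_one_subject_out":
        for s in dataset.subject_ids:
            test = all_idx[subjects == s]
            train = all_idx[subjects != s]
            folds.append(Fold(s, train, test, subject_id=s))
    else:  # two_fold
        if spec.split_rule == "matched":
            a, b = _matched_split(dataset)
        elif spec.split_rule == "hand_size_grouped":
            ids = sorted(dataset.subject_ids,
                         key=lambda s: (dataset.subjects[s].hand_size, s))
            half = len(ids) // 2
            a, b = set(ids[:half]), set(ids[half:])
        else:
            a = {s for s in dataset.subject_ids
                 if dataset.subjects[s].age_group == "young"}
            b = set(dataset.subject_ids) - a
        in_a = np.isin(subjects, sorted(a))
        folds.append(Fold("test_half_b", all_idx[in_a], all_idx[~in_a]))
        folds.append(Fold("test_half_a", all_idx[~in_a], all_idx[in_a]))
    # sanity: folds partition the trials
    test_union = np.concatenate([f.test_idx for f in folds])
    if len(np.unique(test_union)) != dataset.n_trials:
        raise AssertionError("test folds do not partition the dataset")
    return folds


# ---------------------------------------------------------------------------
# Per-fold classifier pipelines
# ---------------------------------------------------------------------------

@dataclass
class _PreparedFold:
    """Label-independent per-fold state, reusable across permutations."""

    fold: Fold
    template: dtw.Template | None
    train_inputs: object     # feature matrix (svm) or trial list (lstm)
    test_inputs: object
    gram_train: np.ndarray | None = None   # inner products, svm_dtw only
    gram_test: np.ndarray | None = None


def _prepare_fold(dataset: Dataset, fold: Fold, spec: CVSpec) -> _PreparedFold:
    train_trials = [dataset.trials[i] for i in fold.train_idx]
    test_trials = [dataset.trials[i] for i in fold.test_idx]
    template = None
    if spec.classifier in ("svm_dtw", "lstm_dtw"):
        template, aligned_train, aligned_test = dtw.align_dataset(
            train_trials, test_trials)
        train_fold_subjects = {t.subject_id for t in train_trials}
        if template.provenance["subject_id"] not in train_fold_subjects:
            raise AssertionError(
                "template leakage: provenance outside the training fold")
        if spec.classifier == "svm_dtw":
            feats_train = dtw.to_feature_matrix(aligned_train)
            feats_test = dtw.to_feature_matrix(aligned_test)
            return _PreparedFold(fold, template, feats_train, feats_test,
                                 gram_train=feats_train @ feats_train.T,
                                 gram_test=feats_test @ feats_train.T)
        return _PreparedFold(fold, template, aligned_train, aligned_test)
    return _PreparedFold(fold, None, train_trials, test_trials)


def _fit_predict(prep: _PreparedFold, train_labels: np.ndarray,
                 spec: CVSpec) -> np.ndarray:
    if len(set(train_labels.tolist())) < 2:
        warnings.warn(f"fold {prep.fold.name}: single-class training labels")
        return np.repeat(train_labels[0], len(prep.fold.test_idx))
    if spec.classifier == "svm_dtw":
        # Gram matrices are label-independent, so refits (as in the
        # permutation test) reuse the cached inner products
        return svm.fit_predict_gram(prep.gram_train, train_labels,
                                    prep.gram_test)
    params = spec.lstm_params or TrainingParams()
    arch = spec.lstm_arch or LstmArchitecture()
    n_channels = prep.train_inputs[0].n_channels
    model = BiLstmClassifier(n_channels, len(set(train_labels.tolist())),
                             arch, seed=params.seed)
    lstm_train(model, prep.train_inputs, train_labels, params)
    pred, _ = model.predict(prep.test_inputs)
    return pred


def _run_prepared(dataset: Dataset, preps: list[_PreparedFold], spec: CVSpec,
                  labels: np.ndarray) -> CVResult:
    classes = sorted(set(labels.tolist()))
    true_all, pred_all, subj_all = [], [], []
    templates = []
    for prep in preps:
        pred = _fit_predict(prep, labels[prep.fold.train_idx], spec)
        true_all.append(labels[prep.fold.test_idx])
        pred_all.append(np.asarray(pred))
        subj_all.append(np.array([dataset.trials[i].subject_id
                                  for i in prep.fold.test_idx]))
        if prep.template is not None:
            templates.append(prep.template)
    return CVResult(classes=classes,
                    true=np.concatenate(true_all),
                    pred=np.concatenate(pred_all),
                    test_subjects=np.concatenate(subj_all),
                    templates=templates)


def run_cv(dataset: Dataset, spec: CVSpec) -> CVResult:
    """Run the full cross-validation: per fold, fit on the training split
    (template selection included, for the DTW pipelines) and predict the
    held-out trials; pool predictions over all folds."""
    folds = make_folds(dataset, spec)
    preps = [_prepare_fold(dataset, f, spec) for f in folds]
    return _run_prepared(dataset, preps, spec, dataset.labels())


def permutation_test(dataset: Dataset, spec: CVSpec,
                     n_permutations: int = 1000,
                     seed: int = 0) -> PermutationResult:
    """Estimate the chance-level DA distribution.

    Each permutation reassigns the task labels randomly over all trials
    (preserving class counts) and reruns the cross-validation.  Alignment
    is label-independent and folds are fixed, so per-fold templates and
    features are prepared once and only the classifier is refit.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    folds = make_folds(dataset, spec)
    preps = [_prepare_fold(dataset, f, spec) for f in folds]
    labels = dataset.labels()
    das = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = labels[rng.permutation(len(labels))]
        das[p] = _run_prepared(dataset, preps, spec, perm).da
    ci = (float(np.percentile(das, 2.5)), float(np.percentile(das, 97.5)))
    return PermutationResult(das=das, ci=ci)


# ---------------------------------------------------------------------------
# Condition comparison and reporting
# ---------------------------------------------------------------------------

def compare_conditions(per_subject_da_a, per_subject_da_b,
                       n_comparisons: int = 1) -> float:
    """Paired Wilcoxon signed-rank test on per-subject DAs, two-sided,
    Bonferroni-adjusted by ``n_comparisons``.

    Uses the exact null distribution for n <= 25 when there are no ties or
    zero differences, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(per_subject_da_a, dtype=float)
    b = np.asarray(per_subject_da_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need paired 1-D vectors of length >= 5")
    diff = a - b
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    method = "exact" if len(a) <= 25 else "approx"
    try:
        _, p = stats.wilcoxon(a, b, method=method)
    except ValueError:
        _, p = stats.wilcoxon(a, b, method="approx")
    return float(min(1.0, p * n_comparisons))


def sensitivity_table(results: dict[tuple[str, str], CVResult]) -> pd.DataFrame:
    """Per-task sensitivity (recall, %) with across-subject SE.

    ``results`` maps (classifier, scheme) to a CVResult; the table has one
    row per movement task and one "mean (SE)" column per condition.
    """
    table = {}
    for (classifier, scheme), res in results.items():
        col = {}
        for task in TASKS:
            per_subj = []
            for s in np.unique(res.test_subjects):
                m = (res.test_subjects == s) & (res.true == task)
                if m.any():
                    per_subj.append(100.0 * np.mean(res.pred[m] == res.true[m]))
            per_subj = np.array(per_subj)
            se = (per_subj.std(ddof=1) / np.sqrt(len(per_subj))
                  if len(per_subj) > 1 else float("nan"))
            col[task] = f"{per_subj.mean():.1f} ({se:.1f})"
        table[f"{classifier}/{scheme}"] = col
    return pd.DataFrame(table).reindex(list(TASKS))
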