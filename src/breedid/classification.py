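"""Breed assignment: five classifiers, the KSR consensus, and evaluation.

The assignment stage trains a classifier on the reference population's
genotypes at the selected marker panel (raw allele counts 0/1/2 as
features, breed codes as labels) and predicts the breed of each test
animal.  Five standard learners are supported — k-nearest neighbours,
RBF support-vector machine, random forest, Gaussian naive Bayes, and a
single-hidden-layer neural network — plus the KSR consensus of KNN, SVM
and RF: a sample keeps the breed that at least two of the three agree on,
and falls back to the KNN call when all three disagree.

Evaluation repeats each classification R times (seed = base_seed + r for
the stochastic learners) and reports the accuracy

    Accuracy = (1/R) * sum_r  N_T / (N_T + N_F)

in percent, its standard error (sample SD / sqrt(R)), and the per-breed
incorrect-assignment counts with full confusion matrices.  Deterministic
learners (KNN, SVM, NB) repeat bitwise identically, so their SE is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import BreedLabels, GenotypeMatrix
from .informativeness import MarkerPanel

__all__ = [
    "CLASSIFIERS",
    "KSR_COMPONENTS",
    "ClassifierConfig",
    "TrainedModel",
    "PredictionSet",
    "EvaluationReport",
    "train",
    "predict",
    "ksr_consensus",
    "align_to_panel",
    "evaluate",
    "subsample_reference",
    "per_breed_confusion",
    "accuracy_percent",
    "error_rate_percent",
]

CLASSIFIERS = ("knn", "svm", "rf", "nb", "ann")
KSR_COMPONENTS = ("knn", "svm", "rf")

_DEFAULTS: dict[str, dict] = {
    "knn": {"k": 5},
    "svm": {"kernel": "rbf", "cost": 1.0, "gamma": "auto"},  # gamma=1/n_features
    "rf": {"n_trees": 500, "max_features": "sqrt"},
    "nb": {},
    "ann": {"hidden_size": 10, "max_iterations": 200, "weight_decay": 0.0},
}

STOCHASTIC = frozenset({"rf", "ann"})


@dataclass
class ClassifierConfig:
    """One learner plus its hyperparameters and (optional) seed."""

    method: str
    params: dict = field(default_factory=dict)
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in CLASSIFIERS:
            raise ValueError(f"unknown method {self.method!r}; choose from {CLASSIFIERS}")
        merged = dict(_DEFAULTS[self.method])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(f"unknown {self.method} parameters: {sorted(unknown)}")
        merged.update(self.params)
        self.params = merged
        if self.method == "knn" and self.params["k"] < 1:
            raise ValueError("knn k must be >= 1")
        if self.method == "rf" and self.params["n_trees"] < 1:
            raise ValueError("rf n_trees must be >= 1")

    def build_estimator(self):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.naive_bayes import GaussianNB
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.neural_network import MLPClassifier
        from sklearn.svm import SVC

        p = self.params
        if self.method == "knn":
            return KNeighborsClassifier(n_neighbors=p["k"])
        if self.method == "svm":
            return SVC(kernel=p["kernel"], C=p["cost"], gamma=p["gamma"])
        if self.method == "rf":
            return RandomForestClassifier(
                n_estimators=p["n_trees"],
                max_features=p["max_features"],
                random_state=self.random_seed,
            )
        if self.method == "nb":
            return GaussianNB()
        return MLPClassifier(
            hidden_layer_sizes=(p["hidden_size"],),
            max_iter=p["max_iterations"],
            alpha=p["weight_decay"],
            solver="lbfgs",
            random_state=self.random_seed,
        )


@dataclass
class TrainedModel:
    """Opaque fitted classifier bound to the marker panel it was trained on."""

    config: ClassifierConfig
    estimator: object
    classes: list[str]
    panel_snp_ids: list[str] | None = None


@dataclass
class PredictionSet:
    """Per-sample breed calls for one or more methods."""

    samples: list[str]
    calls: dict[str, np.ndarray]  # method -> array of breed codes

    def __post_init__(self) -> None:
        for m, arr in self.calls.items():
            if len(arr) != len(self.samples):
                raise ValueError(f"{m}: {len(arr)} calls for {len(self.samples)} samples")

    def for_method(self, method: str) -> np.ndarray:
        return self.calls[method]


def align_to_panel(g: GenotypeMatrix, panel: MarkerPanel) -> np.ndarray:
    """Genotype codes restricted to the panel's SNPs, in panel order."""
    g.assert_complete("classification")
    lookup = {s.snp_id: j for j, s in enumerate(g.snps)}
    missing = [sid for sid in panel.snp_ids if sid not in lookup]
    if missing:
        raise KeyError(
            f"{len(missing)} panel SNPs absent from genotype matrix "
            f"(first few: {missing[:5]})"
        )
    idx = [lookup[sid] for sid in panel.snp_ids]
    return g.codes[:, idx].astype(float)


def train(
    config: ClassifierConfig,
    X: np.ndarray,
    y: Sequence[str],
    panel: MarkerPanel | None = None,
) -> TrainedModel:
    """Fit one classifier on reference genotypes (rows) x panel SNPs (cols)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 breeds")
    counts = {c: int((y == c).sum()) for c in classes}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"breeds with no training samples: {empty}")
    est = config.build_estimator()
    est.fit(X, y)
    return TrainedModel(
        config=config,
        estimator=est,
        classes=classes,
        panel_snp_ids=panel.snp_ids if panel is not None else None,
    )


def predict(model: TrainedModel, X_test: np.ndarray, sample_ids: Sequence[str]) -> PredictionSet:
    """Breed call for each test sample from one trained classifier."""
    X_test = np.asarray(X_test, dtype=float)
    if len(sample_ids) != X_test.shape[0]:
        raise ValueError("sample_ids length does not match test matrix rows")
    if X_test.shape[0] == 0:
        calls = np.asarray([], dtype=object)
    else:
        calls = np.asarray(model.estimator.predict(X_test))
    return PredictionSet(list(sample_ids), {model.config.method: calls})


def ksr_consensus(
    p_knn: PredictionSet, p_svm: PredictionSet, p_rf: PredictionSet
) -> PredictionSet:
    """Consensus of KNN/SVM/RF: any two agreeing win; otherwise the KNN call."""
    if not (p_knn.samples == p_svm.samples == p_rf.samples):
        raise ValueError("KSR inputs must cover the same samples in the same order")
    knn, svm, rf = p_knn.for_method("knn"), p_svm.for_method("svm"), p_rf.for_method("rf")
    out = []
    for a, b, c in zip(knn, svm, rf):
        if b == c:  # covers unanimity and svm+rf agreement
            out.append(b)
        else:  # a==b, a==c, or total disagreement all yield the KNN call
            out.append(a)
    return PredictionSet(list(p_knn.samples), {"ksr": np.asarray(out)})


def accuracy_percent(n_t: float, n_f: float) -> float:
    """N_T / (N_T + N_F) as a percentage."""
    return 100.0 * n_t / (n_t + n_f)


def error_rate_percent(mean_incorrect: float, n_animals: float) -> float:
    """Mean incorrect-assignment count over the group size, in percent."""
    return 100.0 * mean_incorrect / n_animals


@dataclass
class EvaluationReport:
    """Replicated evaluation of one method: accuracy, SE, per-breed errors."""

    method: str
    replicates: int
    accuracies: np.ndarray  # percent, one per replicate
    incorrect_by_breed: pd.DataFrame  # replicates x breeds counts
    confusions: list[pd.DataFrame]
    n_test: int

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_se(self) -> float:
        if self.replicates < 2:
            return 0.0
        return float(self.accuracies.std(ddof=1) / np.sqrt(self.replicates))

    @property
    def incorrect_mean(self) -> pd.Series:
        return self.incorrect_by_breed.mean(axis=0)

    @property
    def incorrect_se(self) -> pd.Series:
        if self.replicates < 2:
            return self.incorrect_by_breed.iloc[0] * 0.0
        return self.incorrect_by_breed.std(axis=0, ddof=1) / np.sqrt(self.replicates)

    def summary(self) -> pd.DataFrame:
        """Per-breed mean (SE) incorrect counts plus the total row."""
        df = pd.DataFrame(
            {"incorrect_mean": self.incorrect_mean, "incorrect_se": self.incorrect_se}
        )
        df.loc["Total"] = [
            self.incorrect_by_breed.sum(axis=1).mean(),
            (
                self.incorrect_by_breed.sum(axis=1).std(ddof=1) / np.sqrt(self.replicates)
                if self.replicates > 1
                else 0.0
            ),
        ]
        return df


def per_breed_confusion(
    calls: np.ndarray, truth: np.ndarray, breeds: Sequence[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Incorrect counts per true breed and the full confusion matrix.

    The confusion matrix rows are true breeds, columns predicted breeds;
    off-diagonal row sums equal the per-breed incorrect counts.
    """
    breeds = list(breeds)
    extra = [b for b in np.unique(calls) if b not in breeds]
    cols = breeds + extra
    conf = pd.DataFrame(0, index=breeds, columns=cols, dtype=int)
    for t, p in zip(truth, calls):
        conf.loc[t, p] += 1
    diag = pd.Series({b: conf.loc[b, b] for b in breeds})
    incorrect = conf.sum(axis=1) - diag
    return incorrect, conf


def evaluate(
    reference: GenotypeMatrix,
    ref_labels: BreedLabels,
    test: GenotypeMatrix,
    test_labels: BreedLabels,
    panel: MarkerPanel,
    methods: Sequence[str] = ("knn", "svm", "rf", "ksr"),
    replicates: int = 50,
    base_seed: int = 0,
    configs: dict[str, ClassifierConfig] | None = None,
) -> dict[str, EvaluationReport]:
    """Replicated train/predict evaluation for each requested method.

    Replicate r seeds the stochastic learners with ``base_seed + r``;
    deterministic learners repeat identically (their SE is exactly 0).
    Requesting ``ksr`` implies training its three component methods.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    overlap = set(reference.samples) & set(test.samples)
    if overlap:
        raise ValueError(f"reference and test share samples: {sorted(overlap)[:5]}")
    methods = list(methods)
    unknown = [m for m in methods if m not in CLASSIFIERS + ("ksr",)]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")

    to_train = [m for m in methods if m != "ksr"]
    if "ksr" in methods:
        to_train += [m for m in KSR_COMPONENTS if m not in to_train]

    X_ref = align_to_panel(reference, panel)
    y_ref = ref_labels.labels_for(reference.samples)
    X_test = align_to_panel(test, panel)
    y_test = test_labels.labels_for(test.samples)
    breeds = list(ref_labels.breeds)

    acc: dict[str, list[float]] = {m: [] for m in methods}
    inc: dict[str, list[pd.Series]] = {m: [] for m in methods}
    confs: dict[str, list[pd.DataFrame]] = {m: [] for m in methods}

    for r in range(replicates):
        seed = base_seed + r
        preds: dict[str, PredictionSet] = {}
        for m in to_train:
            cfg = (
                configs[m]
                if configs and m in configs
                else ClassifierConfig(method=m)
            )
            if m in STOCHASTIC:
                cfg = ClassifierConfig(method=m, params=dict(cfg.params), random_seed=seed)
            model = train(cfg, X_ref, y_ref, panel=panel)
            preds[m] = predict(model, X_test, test.samples)
        if "ksr" in methods:
            preds["ksr"] = ksr_consensus(preds["knn"], preds["svm"], preds["rf"])
        for m in methods:
            calls = preds[m].for_method(m)
            n_t = int((calls == y_test).sum())
            n_f = len(y_test) - n_t
            acc[m].append(accuracy_percent(n_t, n_f))
            incorrect, conf = per_breed_confusion(calls, y_test, breeds)
            assert int(incorrect.sum()) == n_f
            inc[m].append(incorrect)
            confs[m].append(conf)

    return {
        m: EvaluationReport(
            method=m,
            replicates=replicates,
            accuracies=np.asarray(acc[m]),
            incorrect_by_breed=pd.DataFrame(inc[m]).reset_index(drop=True),
            confusions=confs[m],
            n_test=len(y_test),
        )
        for m in methods
    }


def subsample_reference(
    reference: GenotypeMatrix,
    labels: BreedLabels,
    per_breed_n: int,
    repeats: int = 3,
    seed: int = 0,
) -> list[tuple[GenotypeMatrix, BreedLabels]]:
    """Draw ``repeats`` reference subsets with exactly ``per_breed_n`` samples
    per breed, without replacement, reproducibly."""
    by_breed = {b: [s for s in reference.samples if labels.mapping.get(s) == b]
                for b in labels.breeds}
    short = {b: len(v) for b, v in by_breed.items() if len(v) < per_breed_n}
    if short:
        raise ValueError(f"per_breed_n={per_breed_n} exceeds available samples: {short}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        chosen: list[str] = []
        for b in labels.breeds:
            pool = by_breed[b]
            pick = rng.choice(len(pool), size=per_breed_n, replace=False)
            chosen.extend(pool[i] for i in sorted(pick))
        sub = reference.take_samples(chosen)
        out.append((sub, BreedLabels({s: labels.mapping[s] for s in chosen},
                                     breeds=list(labels.breeds))))
    return out
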