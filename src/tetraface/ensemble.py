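"""Under-sampled SVM ensemble for interface residue-pair scoring.

Interface residue pairs are vastly outnumbered by non-interface pairs, so
the classifier is an ensemble built by random under-sampling: the negatives
are sampled ``n_models`` times (without replacement within a draw,
independently across draws) to the size of the positive set, each balanced
set trains one RBF-kernel C-SVM with probability output, and the fused
score of a pair is the sum of the member probabilities.  The reported score
divides that sum by ``n_models`` so it lies in [0, 1]; the ranking — and
therefore every top-t metric — is unchanged by the normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class EnsembleConfig:
    """Configuration of the under-sampled SVM ensemble."""

    n_models: int = 10
    negatives_per_set: int | None = None  # default: number of positives
    C: float = 1.0
    gamma: float | str = "median"  # 'median' heuristic, 'scale', or a float
    disjoint_negatives: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.negatives_per_set is not None and self.negatives_per_set < 1:
            raise ValueError("negatives_per_set must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class InterfaceRanking:
    """Residue pairs of one chain pair sorted by descending ensemble score.

    Ties break by (chain-1 index ascending, chain-2 index ascending).
    """

    chain_pair: tuple[str, str]
    pairs: np.ndarray  # (n, 2) residue-index pairs, ranked
    scores: np.ndarray  # matching normalized scores, descending

    def top(self, t: int) -> "InterfaceRanking":
        if t < 1:
            raise ValueError("t must be >= 1")
        if t > len(self.scores):
            warnings.warn(
                f"t={t} exceeds the {len(self.scores)} candidate pairs; "
                "returning all",
                stacklevel=2,
            )
            t = len(self.scores)
        return InterfaceRanking(self.chain_pair, self.pairs[:t], self.scores[:t])


def undersample_sets(
    positives: np.ndarray,
    negatives: np.ndarray,
    config: EnsembleConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build ``n_models`` balanced (X, y) training sets.

    Each set is all positives plus ``negatives_per_set`` negatives drawn
    without replacement; draws are independent across sets (negatives may
    recur between sets) unless ``disjoint_negatives`` is set.
    """
    config = config or EnsembleConfig()
    positives = np.asarray(positives, float)
    negatives = np.asarray(negatives, float)
    n_neg = config.negatives_per_set or len(positives)
    rng = np.random.default_rng(config.seed)
    total_needed = n_neg * config.n_models if config.disjoint_negatives else n_neg
    if len(negatives) < total_needed:
        raise ValueError(
            f"need {total_needed} negatives, have {len(negatives)}"
        )
    if config.disjoint_negatives:
        pool = rng.permutation(len(negatives))
        picks = [
            pool[m * n_neg : (m + 1) * n_neg] for m in range(config.n_models)
        ]
    else:
        picks = [
            rng.choice(len(negatives), size=n_neg, replace=False)
            for _ in range(config.n_models)
        ]
    sets = []
    for idx in picks:
        X = np.concatenate([positives, negatives[idx]])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(idx))])
        sets.append((X, y.astype(int)))
    return sets


def _median_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median heuristic: gamma = 1 / median squared pairwise distance."""
    sub = X if len(X) <= 500 else X[rng.choice(len(X), 500, replace=False)]
    diffs = sub[:, None, :] - sub[None, :, :]
    d2 = (diffs**2).sum(axis=-1)
    med = float(np.median(d2[np.triu_indices(len(sub), k=1)]))
    return 1.0 / med if med > 0 else 1.0


@dataclass
class SvmEnsemble:
    """Fitted ensemble: shared scaler plus n probability-calibrated SVMs."""

    config: EnsembleConfig
    scaler: StandardScaler
    models: list[CalibratedClassifierCV] = field(default_factory=list)

    def score(self, X: np.ndarray, normalized: bool = True) -> np.ndarray:
        """Fused interface score per row of X (920-d pair vectors)."""
        X = np.atleast_2d(np.asarray(X, float))
        Xs = self.scaler.transform(X)
        total = np.zeros(len(X))
        for m in self.models:
            pos = list(m.classes_).index(1)
            total += m.predict_proba(Xs)[:, pos]
        return total / len(self.models) if normalized else total

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SvmEnsemble":
        return joblib.load(path)


def train_ensemble(
    positives: np.ndarray,
    negatives: np.ndarray,
    config: EnsembleConfig | None = None,
) -> SvmEnsemble:
    """Under-sample, fit the scaler and train the member SVMs.

    Features are standardized with statistics fit on the union of the
    positives and every sampled negative; each member is an RBF C-SVM with
    sigmoid-calibrated probability output.
    """
    config = config or EnsembleConfig()
    if len(positives) == 0:
        raise ValueError("no positive samples to train on")
    sets = undersample_sets(positives, negatives, config)
    union = np.concatenate([X for X, _ in sets])
    scaler = StandardScaler().fit(union)
    rng = np.random.default_rng(config.seed)
    if config.gamma == "median":
        gamma = _median_gamma(scaler.transform(union), rng)
    else:
        gamma = config.gamma
    models = []
    for m, (X, y) in enumerate(sets):
        if len(np.unique(y)) < 2:
            raise ValueError(f"training set {m} has a single class")
        min_class = int(min((y == 1).sum(), (y == 0).sum()))
        if min_class < 2:
            raise ValueError(
                "probability calibration needs at least 2 samples per class"
            )
        svc = CalibratedClassifierCV(
            SVC(C=config.C, kernel="rbf", gamma=gamma,
                random_state=config.seed + m),
            method="sigmoid",
            cv=min(5, min_class),
            ensemble=False,
        )
        svc.fit(scaler.transform(X), y)
        models.append(svc)
    return SvmEnsemble(config=config, scaler=scaler, models=models)


def rank_interface(
    ensemble: SvmEnsemble,
    pair_vectors: np.ndarray,
    pair_indices: np.ndarray,
    chain_pair: tuple[str, str] = ("", ""),
    t: int | None = None,
) -> InterfaceRanking:
    """Rank a chain pair's candidate residue pairs by descending score."""
    pair_indices = np.asarray(pair_indices, int)
    scores = ensemble.score(pair_vectors)
    order = np.lexsort((pair_indices[:, 1], pair_indices[:, 0], -scores))
    ranking = InterfaceRanking(
        chain_pair=chain_pair, pairs=pair_indices[order], scores=scores[order]
    )
    return ranking if t is None else ranking.top(t)
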