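"""Linear-SVM discrimination between MP and non-MP spectra.

A full-grid linear SVM is trained on SNV-pretreated spectra; the magnitude
of its coefficient vector serves as a per-wavenumber feature importance,
from which a handful of discriminative wavenumbers are selected (greedy
top-k with a minimum spacing so one broad band is not picked twice).  A
reduced model retrained on those wavenumbers alone is what gets applied to
discrete-frequency image stacks.

Also here: confusion-matrix metrics (sensitivity, specificity, CCR, MCC)
and a utility that reconstructs the integer confusion matrix from printed
misclassification counts plus rounded sensitivity/specificity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .preprocess import PreprocessSpec, snv_spec
from .spectra import MP, NON_MP, SpectraMatrix, WavenumberGrid

KIND_FULL = "FULL"
KIND_REDUCED = "REDUCED"

# how a model's features are derived from a spectrum / pixel vector
FEAT_PREP_FULL = "prep_full"       # preprocess the full spectrum (FULL models)
FEAT_VECTOR_SNV = "vector_snv"     # extract raw values, SNV across the vector
FEAT_PREP_EXTRACT = "prep_extract" # preprocess full spectrum, then extract


# ---------------------------------------------------------------------------
# model container

@dataclass
class DiscriminantModel:
    """Linear decision rule: label MP when w . x + bias > 0 (tie -> NON_MP).

    ``weights`` is one coefficient per entry of ``wavenumbers_used``; the
    features x are the preprocessed (by ``prep``) intensities at those
    wavenumbers.
    """

    kind: str
    wavenumbers_used: np.ndarray
    weights: np.ndarray
    bias: float
    prep: PreprocessSpec
    feature_mode: str = FEAT_PREP_FULL
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers_used = np.asarray(self.wavenumbers_used, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.wavenumbers_used.shape:
            raise ValueError("one weight per wavenumber required")
        if self.kind not in (KIND_FULL, KIND_REDUCED):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.feature_mode not in (FEAT_PREP_FULL, FEAT_VECTOR_SNV,
                                     FEAT_PREP_EXTRACT):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "wavenumbers_used": self.wavenumbers_used.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "prep": self.prep.to_dict(),
            "feature_mode": self.feature_mode,
            "train_meta": self.train_meta,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            kind=d["kind"],
            wavenumbers_used=np.array(d["wavenumbers_used"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            prep=PreprocessSpec.from_dict(d["prep"]),
            feature_mode=d.get("feature_mode", FEAT_PREP_FULL),
            train_meta=d.get("train_meta", {}),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "DiscriminantModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# training

def split_train_test(data: SpectraMatrix, train_fraction: float = 2 / 3,
                     seed: int = 0) -> tuple[SpectraMatrix, SpectraMatrix]:
    """Stratified random split: per class, floor(train_fraction * n) rows go
    to the training set and the remainder to the test set."""
    if data.labels is None:
        raise ValueError("split requires labeled data")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1); the "
                         "test set must be non-empty")
    labels = np.asarray(data.labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (MP, NON_MP):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = int(math.floor(train_fraction * members.size))
        if n_train == 0 or n_train == members.size:
            raise ValueError("split leaves a class empty on one side")
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return (data.subset(np.sort(np.array(train_idx))),
            data.subset(np.sort(np.array(test_idx))))


def _features(data: SpectraMatrix, prep: PreprocessSpec,
              wavenumbers: np.ndarray | None, feature_mode: str) -> np.ndarray:
    """Feature matrix per the model's feature mode.

    ``prep_full``: preprocess whole spectra (FULL models).
    ``vector_snv``: extract raw intensities at the model wavenumbers, then
    SNV across that short vector -- exactly what an application pixel, which
    only carries those few intensities, can offer.
    ``prep_extract``: preprocess whole spectra, then extract the columns.
    """
    from .preprocess import snv_array

    if feature_mode == FEAT_PREP_FULL:
        return prep.apply_array(data.grid, data.X)
    idx = data.grid.index_of(wavenumbers)
    if feature_mode == FEAT_VECTOR_SNV:
        return snv_array(data.X[:, idx])
    return prep.apply_array(data.grid, data.X)[:, idx]


def train_model(train: SpectraMatrix,
                wavenumbers: Sequence[float] | None = None,
                prep: PreprocessSpec | None = None,
                C: float = 1.0, seed: int = 0,
                feature_mode: str | None = None) -> DiscriminantModel:
    """Fit a linear-kernel maximum-margin classifier (MP = positive class).

    For the FULL model, preprocessing (SNV by default) runs on the whole
    spectrum.  For a REDUCED model the default ``vector_snv`` feature mode
    extracts the raw intensities at ``wavenumbers`` and SNV-normalizes that
    short vector, so development features are defined identically to what a
    discrete-frequency image pixel provides at application time;
    ``prep_extract`` instead preprocesses the full spectrum and then
    extracts.  The fit is deterministic for a fixed input.
    """
    if train.labels is None:
        raise ValueError("training requires labeled data")
    classes = set(train.labels)
    if classes != {MP, NON_MP}:
        raise ValueError(f"need both MP and NON_MP in training data, got {classes}")
    prep = prep if prep is not None else snv_spec()
    wn = None if wavenumbers is None else np.sort(np.asarray(wavenumbers, dtype=float))
    if wn is None:
        feature_mode = FEAT_PREP_FULL
    elif feature_mode is None:
        feature_mode = FEAT_VECTOR_SNV
    X = _features(train, prep, wn, feature_mode)
    y = np.array([1 if l == MP else 0 for l in train.labels])
    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(X, y)
    used = train.grid.values.copy() if wn is None else wn
    return DiscriminantModel(
        kind=KIND_FULL if wn is None else KIND_REDUCED,
        wavenumbers_used=used,
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        prep=prep,
        feature_mode=feature_mode,
        train_meta={
            "seed": seed,
            "C": C,
            "class_counts": {MP: int(y.sum()), NON_MP: int((1 - y).sum())},
        },
    )


def predict(m: DiscriminantModel, x: SpectraMatrix) -> list[str]:
    """Label each spectrum: MP when the decision score is > 0, else NON_MP."""
    if m.kind == KIND_FULL:
        if x.grid != WavenumberGrid(m.wavenumbers_used):
            raise ValueError("spectra grid does not match the model's grid")
        X = m.prep.apply_array(x.grid, x.X)
    elif len(x.grid) == len(m.wavenumbers_used) and x.grid == WavenumberGrid(
            m.wavenumbers_used):
        # already sampled at the model's wavenumbers (e.g. pixel vectors)
        from .preprocess import snv_array
        X = snv_array(x.X) if m.feature_mode == FEAT_VECTOR_SNV \
            else m.prep.apply_array(x.grid, x.X)
    else:
        X = _features(x, m.prep, m.wavenumbers_used, m.feature_mode)
    scores = m.decision_scores(X)
    return [MP if s > 0 else NON_MP for s in scores]


# ---------------------------------------------------------------------------
# feature importance and wavenumber selection

@dataclass
class ImportanceProfile:
    wavenumbers: np.ndarray
    importance: np.ndarray          # |w_j|
    signed_weights: np.ndarray      # retained for plotting

    def __post_init__(self) -> None:
        if not (len(self.wavenumbers) == len(self.importance)
                == len(self.signed_weights)):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.importance < 0):
            raise ValueError("importance must be non-negative")


def feature_importance(m: DiscriminantModel) -> ImportanceProfile:
    """Coefficient-magnitude importance per wavenumber (full models only)."""
    if m.kind != KIND_FULL:
        raise ValueError("feature importance is defined on the full-grid model")
    return ImportanceProfile(m.wavenumbers_used.copy(), np.abs(m.weights),
                             m.weights.copy())


def select_wavenumbers(p: ImportanceProfile, k: int = 4,
                       min_separation: float = 20.0) -> list[float]:
    """Greedy top-k importance peaks with pairwise spacing >= min_separation.

    Returned in descending importance order.  With min_separation 0 this is
    a plain top-k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(p.importance)[::-1]
    chosen: list[float] = []
    for j in order:
        w = float(p.wavenumbers[j])
        if all(abs(w - c) >= min_separation for c in chosen):
            chosen.append(w)
        if len(chosen) == k:
            return chosen
    raise ValueError(
        f"separation constraint of {min_separation} cm^-1 admits only "
        f"{len(chosen)} wavenumbers; k={k} is infeasible"
    )


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion matrix with MP as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    ccr: float            # percentage
    mcc: float | None     # None means undefined (a zero factor)

    def rounded(self) -> dict:
        """Display precision: CCR to 2 decimals (percent), the rest to 4."""
        return {
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "ccr_pct": round(self.ccr, 2),
            "mcc": None if self.mcc is None else round(self.mcc, 4),
        }


def confusion_from_labels(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(np.sum((t == MP) & (p == MP))),
        fn=int(np.sum((t == MP) & (p == NON_MP))),
        fp=int(np.sum((t == NON_MP) & (p == MP))),
        tn=int(np.sum((t == NON_MP) & (p == NON_MP))),
    )


def metrics_from_counts(c: ConfusionCounts) -> ClassMetrics:
    P, N = c.tp + c.fn, c.tn + c.fp
    if P == 0 or N == 0:
        raise ValueError("both classes must be present to compute metrics")
    denom_factors = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if 0 in denom_factors:
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(
            math.prod(float(f) for f in denom_factors))
    return ClassMetrics(
        sensitivity=c.tp / P,
        specificity=c.tn / N,
        ccr=100.0 * (c.tp + c.tn) / c.total,
        mcc=mcc,
    )


def reconstruct_confusion(fn: int, fp: int, sensitivity: float,
                          specificity: float, ccr: float | None = None,
                          rounding_digits: int = 4,
                          max_total: int = 5000) -> ConfusionCounts:
    """Recover the integer confusion matrix behind printed summary figures.

    Enumerates class totals P and N such that tp/(tp+fn) and tn/(tn+fp)
    round (at ``rounding_digits``) to the printed sensitivity/specificity.
    If several (P, N) pairs survive and a printed CCR (percent, 2 decimals)
    is supplied, it breaks the tie; otherwise an ambiguity error lists the
    candidates.
    """
    if not (0 < sensitivity < 1 and 0 < specificity < 1):
        raise ValueError(
            "printed sensitivity/specificity of exactly 0 or 1 leave the "
            "class totals unconstrained (ambiguous)")
    P_cands = [P for P in range(fn + 1, max_total)
               if round((P - fn) / P, rounding_digits) == round(sensitivity,
                                                               rounding_digits)]
    N_cands = [N for N in range(fp + 1, max_total)
               if round((N - fp) / N, rounding_digits) == round(specificity,
                                                               rounding_digits)]
    if not P_cands or not N_cands:
        raise ValueError("no integer class totals are consistent with the "
                         "printed sensitivity/specificity")
    candidates = [ConfusionCounts(tp=P - fn, fn=fn, fp=fp, tn=N - fp)
                  for P in P_cands for N in N_cands]
    if len(candidates) > 1 and ccr is not None:
        candidates = [c for c in candidates
                      if round(100.0 * (c.tp + c.tn) / c.total, 2) == round(ccr, 2)]
        if not candidates:
            raise ValueError("no candidate matrix reproduces the printed CCR")
    if len(candidates) > 1:
        listing = [(c.tp + c.fn, c.tn + c.fp) for c in candidates]
        raise ValueError(f"ambiguous reconstruction; candidate (P, N): {listing}")
    return candidates[0]
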