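"""Multi-target moving-average featurization and forward-stepwise selection.

The multi-target trick: a single classifier handles many enzyme subclasses
because each (drug, subclass) pair is encoded jointly.  For every selected
base descriptor MD the feature vector carries the triple

    (MD, <MD>, DMD)    with DMD = MD - <MD>,

where ``<MD>`` is the arithmetic mean of the descriptor over the pairs of
that enzyme subclass — the Box–Jenkins-style moving-average reference value —
and ``DMD`` is the deviation of the drug from its target class.  Class means
are learned on the training partition only and then frozen, so validation
labels never leak into the features.

Descriptor selection follows the classic forward-stepwise scheme: alternate
forward entry and backward removal of base descriptors until neither
criterion fires, scoring each move with a likelihood-ratio test of a
logistic-regression surrogate (p-to-enter 0.05, p-to-remove 0.10 by
default).  The three feature forms of a selected base descriptor always
enter the downstream model together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .chemio import PairRecord
from .descriptors import REGISTRY_VERSION, DescriptorVector
from .errors import DegenerateInputError, EmptyClassError


@dataclass(frozen=True)
class TargetClassProfile:
    """Per-enzyme-subclass descriptor means ``<MD>``."""

    ec_family: str
    means: dict[str, float]
    n_pairs: int

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("a profile needs at least one contributing record")
        if not all(np.isfinite(v) for v in self.means.values()):
            raise ValueError(f"non-finite mean in profile {self.ec_family}")


@dataclass
class MTFeatureVector:
    """(MD, <MD>, DMD) triples for one (drug, subclass) pair."""

    drug_id: str
    ec_family: str
    names: tuple[str, ...]  # selected base descriptor names, in order
    values: np.ndarray  # length 3 * len(names): (MD, mean, DMD) per name

    def __post_init__(self):
        if len(self.values) != 3 * len(self.names):
            raise ValueError("feature vector length must be 3x the descriptor count")


@dataclass
class SelectionResult:
    """Outcome of forward-stepwise descriptor selection with its step log."""

    selected: list[str]
    log: list[dict] = field(default_factory=list)


def feature_column_names(selected: Sequence[str]) -> list[str]:
    """Column names of the expanded feature table: MD, <MD>, DMD per descriptor."""
    cols = []
    for name in selected:
        cols += [f"{name}", f"{name}__mean", f"{name}__dmd"]
    return cols


def build_class_profiles(
    records: Sequence[PairRecord],
    descriptor_rows: pd.DataFrame,
    contributors: Literal["all", "interacting"] = "all",
) -> dict[str, TargetClassProfile]:
    """Arithmetic per-subclass descriptor means over the given records.

    ``descriptor_rows`` is indexed like ``records`` (one row per record, one
    column per descriptor).  ``contributors`` chooses whether all pairs of a
    subclass or only the interacting ones define the class mean; the default
    uses all pairs.
    """
    if len(records) != len(descriptor_rows):
        raise ValueError("records and descriptor rows differ in length")
    df = descriptor_rows.reset_index(drop=True).copy()
    df["__ec"] = [r.ec_family for r in records]
    if contributors == "interacting":
        mask = np.array([r.label == 1 for r in records])
        df = df[mask]
    profiles: dict[str, TargetClassProfile] = {}
    for ec, grp in df.groupby("__ec", sort=True):
        means = grp.drop(columns="__ec").mean(axis=0)
        profiles[str(ec)] = TargetClassProfile(
            ec_family=str(ec), means=means.to_dict(), n_pairs=len(grp)
        )
    if not profiles:
        raise EmptyClassError("no records, no profiles")
    return profiles


def get_profile(profiles: dict[str, TargetClassProfile], ec_family: str) -> TargetClassProfile:
    try:
        return profiles[ec_family]
    except KeyError:
        raise EmptyClassError(f"no profile for subclass {ec_family!r}") from None


def featurize_pair(
    dv: DescriptorVector | dict[str, float],
    profile: TargetClassProfile,
    selected: Sequence[str],
    drug_id: str = "",
) -> MTFeatureVector:
    """Expand one (drug, subclass) pair into its (MD, <MD>, DMD) triples."""
    values = dv.values if isinstance(dv, DescriptorVector) else dv
    out = np.empty(3 * len(selected), dtype=float)
    for k, name in enumerate(selected):
        if name not in values:
            raise KeyError(f"descriptor {name!r} missing from descriptor vector")
        if name not in profile.means:
            raise KeyError(f"descriptor {name!r} missing from profile {profile.ec_family}")
        md = float(values[name])
        mean = float(profile.means[name])
        out[3 * k : 3 * k + 3] = (md, mean, md - mean)
    return MTFeatureVector(
        drug_id=drug_id, ec_family=profile.ec_family, names=tuple(selected), values=out
    )


class MovingAverageFeaturizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer for the multi-target moving-average features.

    fit(X, y=None)
        ``X`` is a DataFrame with one descriptor column per base descriptor
        plus an ``ec_family`` column; class means are learned from these rows
        (the training partition).  With ``contributors="interacting"`` the
        binary ``y`` restricts contributors to interacting pairs.
    transform(X)
        expands every row into (MD, <MD>, DMD) triples against the frozen
        profile of its ``ec_family``.

    Attributes
    ----------
    profiles_ : dict[str, TargetClassProfile]
    feature_names_out_ : list[str]
    """

    def __init__(
        self,
        descriptor_names: Sequence[str] | None = None,
        contributors: Literal["all", "interacting"] = "all",
        ec_column: str = "ec_family",
    ):
        self.descriptor_names = descriptor_names
        self.contributors = contributors
        self.ec_column = ec_column

    def _names(self, X: pd.DataFrame) -> list[str]:
        if self.descriptor_names is not None:
            return list(self.descriptor_names)
        return [c for c in X.columns if c != self.ec_column]

    def fit(self, X: pd.DataFrame, y=None):
        names = self._names(X)
        if self.ec_column not in X.columns:
            raise ValueError(f"X needs an {self.ec_column!r} column")
        work = X[names + [self.ec_column]].copy()
        if self.contributors == "interacting":
            if y is None:
                raise ValueError("contributors='interacting' requires y in fit")
            work = work[np.asarray(y) == 1]
        profiles: dict[str, TargetClassProfile] = {}
        for ec, grp in work.groupby(self.ec_column, sort=True):
            means = grp[names].mean(axis=0)
            profiles[str(ec)] = TargetClassProfile(
                ec_family=str(ec), means=means.to_dict(), n_pairs=len(grp)
            )
        if not profiles:
            raise EmptyClassError("no rows to build profiles from")
        self.profiles_ = profiles
        self.descriptor_names_ = names
        self.feature_names_out_ = feature_column_names(names)
        self.registry_version_ = REGISTRY_VERSION
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "profiles_")
        names = self.descriptor_names_
        md = X[names].to_numpy(dtype=float)
        fams = X[self.ec_column].astype(str).to_numpy()
        means = np.empty_like(md)
        for i, fam in enumerate(fams):
            prof = get_profile(self.profiles_, fam)
            means[i] = [prof.means[n] for n in names]
        out = np.empty((len(X), 3 * len(names)))
        out[:, 0::3] = md
        out[:, 1::3] = means
        out[:, 2::3] = md - means
        return pd.DataFrame(out, columns=self.feature_names_out_, index=X.index)


# ---------------------------------------------------------------------------
# forward-stepwise selection
# ---------------------------------------------------------------------------

def _null_deviance(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return -2.0 * (n1 * np.log(p) + n0 * np.log(1 - p))


def _deviance(X: np.ndarray, y: np.ndarray) -> float:
    """Deviance of an (unpenalized) logistic fit on standardized columns."""
    if X.shape[1] == 0:
        return _null_deviance(y)
    # unpenalized fit: the LR test statistic needs the true maximum likelihood
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200, tol=1e-6)
    clf.fit(X, y)
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


class ForwardStepwiseSelector(BaseEstimator):
    """Greedy forward-entry / backward-removal feature selection.

    Candidates are columns of ``X`` (base descriptors, typically their DMD
    form).  Each forward step adds the candidate with the largest
    likelihood-ratio improvement of a logistic surrogate, provided its
    chi-square p-value passes ``p_enter``; each backward step removes any
    included feature whose contribution, given the others, has decayed past
    ``p_remove``.  Stops when neither move applies or ``max_features`` is
    reached.  Ties break lexicographically on the feature name, so the
    procedure is deterministic.

    Attributes
    ----------
    selected_ : list[str]
        Selected feature names, in entry order (survivors only).
    log_ : list[dict]
        One entry per step: ``{"step", "action", "name", "p_value"}``.
    """

    def __init__(self, max_features: int = 13, p_enter: float = 0.05, p_remove: float = 0.10):
        self.max_features = max_features
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X: pd.DataFrame, y):
        if self.max_features < 0:
            raise ValueError("max_features must be >= 0")
        if not (self.p_enter <= self.p_remove):
            raise ValueError("p_enter must be <= p_remove to prevent cycling")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        names = [str(c) for c in X.columns]
        live = [n for n in names if X[n].nunique() > 1]
        if not live and names:
            raise DegenerateInputError("all candidate features are constant")
        # standardize once; selection is scale-free but the solver is happier
        Z = (X[live] - X[live].mean()) / X[live].std(ddof=0)
        Zv = {n: Z[n].to_numpy() for n in live}

        selected: list[str] = []
        log: list[dict] = []
        step = 0
        max_steps = 4 * max(len(live), 1)  # hard stop against pathological cycling

        def stack(cols: list[str]) -> np.ndarray:
            if not cols:
                return np.empty((len(y), 0))
            return np.column_stack([Zv[c] for c in cols])

        dev_current = _deviance(stack(selected), y)
        while self.max_features > 0 and step < max_steps:
            moved = False
            # forward entry
            if len(selected) < self.max_features:
                best = None
                for cand in sorted(set(live) - set(selected)):
                    dev = _deviance(stack(selected + [cand]), y)
                    lr = max(dev_current - dev, 0.0)
                    p = float(chi2.sf(lr, df=1))
                    if p < self.p_enter and (best is None or lr > best[1] + 1e-12):
                        best = (cand, lr, p, dev)
                if best is not None:
                    cand, lr, p, dev = best
                    selected.append(cand)
                    dev_current = dev
                    step += 1
                    log.append({"step": step, "action": "enter", "name": cand, "p_value": p})
                    moved = True
            # backward removal
            removed = True
            while removed and selected:
                removed = False
                worst = None
                for name in sorted(selected):
                    dev_wo = _deviance(stack([s for s in selected if s != name]), y)
                    lr = max(dev_wo - dev_current, 0.0)
                    p = float(chi2.sf(lr, df=1))
                    if p > self.p_remove and (worst is None or p > worst[1] - 1e-12):
                        worst = (name, p, dev_wo)
                if worst is not None:
                    name, p, dev_wo = worst
                    selected.remove(name)
                    dev_current = dev_wo
                    step += 1
                    log.append({"step": step, "action": "remove", "name": name, "p_value": p})
                    moved = removed = True
            if not moved:
                break
        self.selected_ = selected
        self.log_ = log
        self.feature_names_in_ = names
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "selected_")
        return np.array([n in self.selected_ for n in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return pd.DataFrame(X)[self.selected_]

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(selected=list(self.selected_), log=list(self.log_))


def forward_stepwise_select(
    features: pd.DataFrame,
    labels,
    max_features: int = 13,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> SelectionResult:
    """Functional wrapper over :class:`ForwardStepwiseSelector`."""
    sel = ForwardStepwiseSelector(max_features=max_features, p_enter=p_enter, p_remove=p_remove)
    sel.fit(features, labels)
    return sel.result()
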