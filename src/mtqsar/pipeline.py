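"""End-to-end multi-target QSAR estimator and the model-search protocol.

:class:`MultiTargetQSAR` wires the stages together behind one scikit-learn
estimator: SMILES → topological descriptors → per-subclass moving-average
features (MD, <MD>, DMD) → forward-stepwise descriptor selection → MLP.
``fit`` receives *training* pairs only; class profiles and standardization
statistics are frozen at fit time, so the validation partition acts as an
external test set.

Fitted models serialize to a single JSON bundle (descriptor registry
version, selected descriptors, class profiles, network weights).  Because
prediction always runs through the package's own forward pass, a reloaded
bundle reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chemio import parse_smiles
from .descriptors import (
    REGISTRY_VERSION,
    DescriptorRegistry,
    compute_descriptors,
    default_registry,
)
from .errors import DescriptorApplicabilityWarning, VersionMismatchError
from .features import (
    ForwardStepwiseSelector,
    MovingAverageFeaturizer,
    SelectionResult,
    TargetClassProfile,
    feature_column_names,
)
from .model import (
    ConfusionStats,
    InteractionMLPClassifier,
    MLPWeights,
    SplitAssignment,
    confusion_stats,
    split_dataset,
)

BUNDLE_SCHEMA_VERSION = 1

PAIR_COLUMNS = ["drug_id", "smiles", "ec_family", "label"]


def _ec_sort_key(ec: str) -> tuple[int, int]:
    a, b = ec.split(".")
    return int(a), int(b)


def descriptor_frame_for_pairs(
    pairs: pd.DataFrame, registry: DescriptorRegistry | None = None
) -> pd.DataFrame:
    """Per-pair descriptor rows (descriptors computed once per unique SMILES)."""
    registry = registry or default_registry()
    unique = pd.unique(pairs["smiles"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DescriptorApplicabilityWarning)
        table = {
            smi: compute_descriptors(parse_smiles(smi), registry).values for smi in unique
        }
    rows = pd.DataFrame([table[s] for s in pairs["smiles"]], columns=registry.names)
    rows.index = pairs.index
    return rows


class MultiTargetQSAR(BaseEstimator, ClassifierMixin):
    """One classifier for all enzyme subclasses.

    Parameters
    ----------
    n_hidden : hidden-layer width of the MLP (paper-scale default 50).
    max_features : cap on selected base descriptors (13 in the reference
        configuration, giving the 39-input network).
    selection : ``"auto"`` to run forward-stepwise selection on the DMD
        features at fit time, or an explicit list of base descriptor names.
    contributors : which pairs define a subclass mean, ``"all"`` or
        ``"interacting"``.
    random_state : master seed for weight initialization.

    Attributes (after fit)
    ----------------------
    selected_ : list of base descriptor names surviving selection.
    selection_result_ : SelectionResult with the step log (None when
        ``selection`` was given explicitly).
    profiles_ : dict ec_family → TargetClassProfile over the full registry.
    clf_ : fitted InteractionMLPClassifier (or None for the degenerate
        majority fallback when no descriptor passes the entry criterion).
    """

    def __init__(
        self,
        n_hidden: int = 50,
        max_features: int = 13,
        selection: str | Sequence[str] = "auto",
        contributors: str = "all",
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        max_iter: int = 300,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.max_features = max_features
        self.selection = selection
        self.contributors = contributors
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, pairs: pd.DataFrame, y=None):
        pairs = pairs.reset_index(drop=True)
        missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
        if missing:
            raise ValueError(f"pair table missing columns {missing}")
        labels = pairs["label"].to_numpy(dtype=int)
        registry = default_registry()
        desc = descriptor_frame_for_pairs(pairs, registry)
        desc_ec = desc.copy()
        desc_ec["ec_family"] = pairs["ec_family"].astype(str)

        featurizer = MovingAverageFeaturizer(
            descriptor_names=registry.names, contributors=self.contributors
        )
        featurizer.fit(desc_ec, labels)
        self.profiles_ = featurizer.profiles_
        self.families_ = sorted(self.profiles_, key=_ec_sort_key)
        self.registry_version_ = registry.version

        self.selection_result_: SelectionResult | None = None
        if isinstance(self.selection, str) and self.selection == "auto":
            expanded = featurizer.transform(desc_ec)
            dmd = expanded[[f"{n}__dmd" for n in registry.names]].copy()
            dmd.columns = registry.names
            selector = ForwardStepwiseSelector(
                max_features=self.max_features,
                p_enter=self.p_enter,
                p_remove=self.p_remove,
            )
            selector.fit(dmd, labels)
            self.selection_result_ = selector.result()
            self.selected_ = list(selector.selected_)
        else:
            unknown = [n for n in self.selection if n not in registry]
            if unknown:
                raise ValueError(f"unknown descriptors in selection: {unknown}")
            self.selected_ = list(self.selection)

        if not self.selected_:
            # no descriptor passed the entry criterion: degenerate majority model
            self.clf_ = None
            self.majority_label_ = int(labels.mean() >= 0.5)
            self.majority_rate_ = float(labels.mean())
            self.n_inputs_ = 0
            self.topology_ = "majority"
            return self

        X = self._expand(desc_ec)
        self.clf_ = InteractionMLPClassifier(
            n_hidden=self.n_hidden, seed=self.random_state, max_iter=self.max_iter
        ).fit(X, labels)
        self.majority_label_ = None
        self.majority_rate_ = None
        self.n_inputs_ = X.shape[1]
        self.topology_ = f"MLP {self.n_inputs_}-{self.n_hidden}-2"
        return self

    def _expand(self, desc_ec: pd.DataFrame) -> np.ndarray:
        """(MD, <MD>, DMD) feature matrix for rows with descriptor + ec columns."""
        names = self.selected_
        md = desc_ec[names].to_numpy(dtype=float)
        fams = desc_ec["ec_family"].astype(str).to_numpy()
        mean_lookup = {
            fam: np.array([self.profiles_[fam].means[n] for n in names])
            for fam in self.profiles_
        }
        means = np.vstack([mean_lookup[f] for f in fams])
        X = np.empty((len(desc_ec), 3 * len(names)))
        X[:, 0::3] = md
        X[:, 1::3] = means
        X[:, 2::3] = md - means
        return X

    @property
    def feature_names_(self) -> list[str]:
        check_is_fitted(self, "selected_")
        return feature_column_names(self.selected_)

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, pairs: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "profiles_")
        pairs = pairs.reset_index(drop=True)
        if self.clf_ is None:
            p = np.full(len(pairs), self.majority_rate_)
            return np.column_stack([1.0 - p, p])
        desc = descriptor_frame_for_pairs(pairs)
        desc["ec_family"] = pairs["ec_family"].astype(str)
        X = self._expand(desc)
        return self.clf_.predict_proba(X)

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        if self.clf_ is None:
            check_is_fitted(self, "profiles_")
            return np.full(len(pairs), self.majority_label_, dtype=int)
        return (self.predict_proba(pairs)[:, 1] > 0.5).astype(int)

    def predict_profile(self, smiles: str) -> dict[str, float]:
        """Interacting-class probability of one drug against every subclass."""
        check_is_fitted(self, "profiles_")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DescriptorApplicabilityWarning)
            dv = compute_descriptors(parse_smiles(smiles))
        if self.clf_ is None:
            return {fam: self.majority_rate_ for fam in self.families_}
        names = self.selected_
        md = np.array([dv.values[n] for n in names])
        X = np.empty((len(self.families_), 3 * len(names)))
        for i, fam in enumerate(self.families_):
            means = np.array([self.profiles_[fam].means[n] for n in names])
            X[i, 0::3] = md
            X[i, 1::3] = means
            X[i, 2::3] = md - means
        return dict(zip(self.families_, self.clf_.predict_proba(X)[:, 1]))

    # -- serialization ------------------------------------------------------

    def to_bundle(self) -> dict:
        check_is_fitted(self, "profiles_")
        bundle = {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "registry_version": self.registry_version_,
            "topology": self.topology_,
            "selected": self.selected_,
            "feature_names": feature_column_names(self.selected_) if self.selected_ else [],
            "contributors": self.contributors,
            "params": {
                "n_hidden": self.n_hidden,
                "max_features": self.max_features,
                "p_enter": self.p_enter,
                "p_remove": self.p_remove,
                "max_iter": self.max_iter,
                "random_state": self.random_state,
            },
            "profiles": {
                fam: {"n_pairs": p.n_pairs, "means": p.means}
                for fam, p in self.profiles_.items()
            },
            "selection_log": self.selection_result_.log if self.selection_result_ else None,
        }
        if self.clf_ is None:
            bundle["majority"] = {
                "label": self.majority_label_, "rate": self.majority_rate_
            }
            bundle["weights"] = None
        else:
            w = self.clf_.weights_
            bundle["majority"] = None
            bundle["weights"] = {
                "x_mean": w.x_mean.tolist(),
                "x_scale": w.x_scale.tolist(),
                "w1": w.w1.tolist(),
                "b1": w.b1.tolist(),
                "w2": w.w2.tolist(),
                "b2": w.b2,
            }
        return bundle

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_bundle()))

    @classmethod
    def from_bundle(cls, bundle: dict) -> "MultiTargetQSAR":
        if bundle.get("schema_version") != BUNDLE_SCHEMA_VERSION:
            raise VersionMismatchError(
                f"bundle schema {bundle.get('schema_version')!r}, "
                f"expected {BUNDLE_SCHEMA_VERSION}"
            )
        if bundle.get("registry_version") != REGISTRY_VERSION:
            raise VersionMismatchError(
                f"bundle registry {bundle.get('registry_version')!r}, "
                f"installed {REGISTRY_VERSION}"
            )
        est = cls(selection=bundle["selected"], **bundle["params"])
        est.selected_ = list(bundle["selected"])
        est.selection_result_ = None
        est.registry_version_ = bundle["registry_version"]
        est.topology_ = bundle["topology"]
        est.profiles_ = {
            fam: TargetClassProfile(ec_family=fam, means=p["means"], n_pairs=p["n_pairs"])
            for fam, p in bundle["profiles"].items()
        }
        est.families_ = sorted(est.profiles_, key=_ec_sort_key)
        if bundle["weights"] is None:
            est.clf_ = None
            est.majority_label_ = bundle["majority"]["label"]
            est.majority_rate_ = bundle["majority"]["rate"]
            est.n_inputs_ = 0
        else:
            w = bundle["weights"]
            clf = InteractionMLPClassifier(
                n_hidden=est.n_hidden, seed=est.random_state, max_iter=est.max_iter
            )
            clf.weights_ = MLPWeights(
                x_mean=np.array(w["x_mean"], dtype=float),
                x_scale=np.array(w["x_scale"], dtype=float),
                w1=np.array(w["w1"], dtype=float),
                b1=np.array(w["b1"], dtype=float),
                w2=np.array(w["w2"], dtype=float),
                b2=float(w["b2"]),
            )
            clf.classes_ = np.array([0, 1])
            clf.n_inputs_ = len(w["x_mean"])
            clf.topology_ = est.topology_
            est.clf_ = clf
            est.majority_label_ = None
            est.majority_rate_ = None
            est.n_inputs_ = clf.n_inputs_
        return est

    @classmethod
    def load(cls, path: str | Path) -> "MultiTargetQSAR":
        return cls.from_bundle(json.loads(Path(path).read_text()))


def save_model(model: MultiTargetQSAR, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> MultiTargetQSAR:
    return MultiTargetQSAR.load(path)


# ---------------------------------------------------------------------------
# repeated split-train-evaluate search
# ---------------------------------------------------------------------------

@dataclass
class SearchEntry:
    """One trained candidate model with its split and statistic battery."""

    model: MultiTargetQSAR
    split: SplitAssignment
    n_hidden: int
    seed: int
    stats_overall: ConfusionStats
    stats_train: ConfusionStats
    stats_valid: ConfusionStats


def evaluate_split(
    model: MultiTargetQSAR, pairs: pd.DataFrame, split: SplitAssignment
) -> dict[str, ConfusionStats]:
    """Confusion statistics on the training, validation and overall partitions."""
    pairs = pairs.reset_index(drop=True)
    pred = model.predict(pairs)
    true = pairs["label"].to_numpy(dtype=int)
    tr, va = split.train_indices, split.valid_indices
    return {
        "overall": confusion_stats(pred, true),
        "training": confusion_stats(pred[tr], true[tr]),
        "validation": confusion_stats(pred[va], true[va]),
    }


def repeat_model_search(
    pairs: pd.DataFrame,
    n_models: int = 10,
    hidden_range: tuple[int, int] = (40, 50),
    top_k: int | None = None,
    seed: int = 0,
    selection: str | Sequence[str] = "once",
    train_fraction: float = 0.70,
    **est_params,
) -> list[SearchEntry]:
    """Train ``n_models`` candidates, each with a fresh random 70/30 split and
    fresh initial weights, and rank them by overall accuracy.

    ``selection="once"`` runs forward-stepwise selection on the first split
    and reuses the selected descriptors for every candidate (descriptor
    selection precedes the topology search); pass ``"auto"`` to re-select per
    model, or an explicit descriptor list.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    pairs = pairs.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    lo, hi = hidden_range
    model_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_models)]
    hidden_sizes = [int(h) for h in rng.integers(lo, hi + 1, size=n_models)]

    fixed_selection: Sequence[str] | str = selection
    if isinstance(selection, str) and selection == "once":
        first_split = split_dataset(len(pairs), train_fraction, model_seeds[0])
        probe = MultiTargetQSAR(
            n_hidden=hidden_sizes[0], random_state=model_seeds[0], **est_params
        )
        probe.fit(pairs.iloc[first_split.train_indices])
        fixed_selection = probe.selected_ if probe.selected_ else "auto"

    entries: list[SearchEntry] = []
    for ms, nh in zip(model_seeds, hidden_sizes):
        split = split_dataset(len(pairs), train_fraction, ms)
        est = MultiTargetQSAR(
            n_hidden=nh, selection=fixed_selection, random_state=ms, **est_params
        )
        est.fit(pairs.iloc[split.train_indices])
        stats = evaluate_split(est, pairs, split)
        entries.append(
            SearchEntry(
                model=est,
                split=split,
                n_hidden=nh,
                seed=ms,
                stats_overall=stats["overall"],
                stats_train=stats["training"],
                stats_valid=stats["validation"],
            )
        )
    entries.sort(key=lambda e: -e.stats_overall.accuracy)
    return entries[: top_k or n_models]
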