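"""Hierarchical, trainable gating tree over per-cell feature vectors.

Node layout (per mode):

- ``HIO``: every detected object -> normal / high_intensity_object
- ``NUCLEI3``: normal objects -> healthy / pyknosed / fragmented
- ``PYKNOSED2``: pyknosed -> mitotic / apoptotic (Annexin signal)
- ``VIA5`` (viability): normal objects -> healthy / early_apoptotic /
  late_apoptotic / necrotic / lysed
- ``TUBULIN`` / ``MITO`` / ``MEMBRANE`` (multiplex): healthy-nucleus cells
  only; the mitochondrial decision is evaluated only in Annexin-negative
  cells and reported ``not_evaluated`` otherwise
- ``FUCCI`` (fucci): healthy-nucleus cells -> red / green / yellow /
  unlabeled

Rule-based fallbacks exist for the HIO, Annexin (PYKNOSED2) and FUCCI
nodes so a pipeline can run untrained; trained nodes override them.
Posterior ties resolve deterministically by fixed class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .features import BODY_SET, FUCCI_EXTRA, NUCLEUS_SET


class GatingError(ValueError):
    pass


class HierarchyError(GatingError):
    """A cell reached a node whose input filter it does not satisfy."""


CLASS_ORDERS: dict[str, list[str]] = {
    "HIO": ["normal", "high_intensity_object"],
    "NUCLEI3": ["healthy", "pyknosed", "fragmented"],
    "PYKNOSED2": ["mitotic", "apoptotic"],
    "VIA5": ["healthy", "early_apoptotic", "late_apoptotic", "necrotic", "lysed"],
    "TUBULIN": ["no_effect", "effect"],
    "MITO": ["not_increased", "increased"],
    "MEMBRANE": ["normal", "permeable"],
    "FUCCI": ["red", "green", "yellow", "unlabeled"],
}

NODE_FEATURES: dict[str, list[str]] = {
    "HIO": ["hoechst_mean", "hoechst_max", "nucleus_area", "nucleus_solidity",
            "nucleus_compactness"],
    "NUCLEI3": [
        "nucleus_area", "nucleus_equivalent_diameter", "nucleus_perimeter",
        "nucleus_compactness", "nucleus_eccentricity", "nucleus_solidity",
        "hoechst_mean", "hoechst_sd", "hoechst_max", "hoechst_cv",
        "fragment_count", "fragment_area_fraction", "radial_intensity_ratio",
    ],
    "PYKNOSED2": [
        "ring_annexin_mean", "body_area", "body_compactness", "body_solidity",
        "nucleus_area", "hoechst_mean", "nucleus_compactness",
    ],
    "VIA5": NUCLEUS_SET + BODY_SET,
    "TUBULIN": ["f488_mean", "f488_sd", "f488_p90", "bf_texture_sd"],
    "MITO": ["f561_mean", "f561_sd", "f561_p90"],
    "MEMBRANE": ["f488_mean", "f488_p90", "body_area", "border_irregularity"],
    "FUCCI": ["nuc488_mean", "nuc561_mean", "f488_mean", "f561_mean"],
}

MODE_NODES = {
    "viability": ["HIO", "NUCLEI3", "PYKNOSED2", "VIA5"],
    "multiplex": ["HIO", "NUCLEI3", "PYKNOSED2", "TUBULIN", "MITO", "MEMBRANE"],
    "fucci": ["HIO", "NUCLEI3", "FUCCI"],
}


@dataclass
class RuleThresholds:
    """Parameters of the rule-based fallback gates. The Annexin and FUCCI
    thresholds should be calibrated per plate from DMSO wells (95th
    percentile of background signal); defaults suit the generator."""

    hio_intensity_k: float = 4.0
    hio_shape_k: float = 2.0
    hio_min_solidity: float = 0.5
    annexin_positive: float = 800.0
    fucci_red: float = 1200.0
    fucci_green: float = 1200.0


@dataclass
class GatingNode:
    node_id: str
    classes: list[str]
    feature_subset: list[str]
    model: RandomForestClassifier
    training_meta: dict = dc_field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
        """Labels + per-class posteriors; ties resolve by class order."""
        X = features[self.feature_subset].to_numpy(dtype=float)
        proba = self.model.predict_proba(X)
        # reorder model classes into the canonical order
        order = [list(self.model.classes_).index(c) for c in self.classes
                 if c in self.model.classes_]
        cols = [self.classes[i] for i, c in enumerate(self.classes)
                if c in self.model.classes_]
        proba = proba[:, order]
        idx = np.argmax(proba, axis=1)  # first max wins -> canonical order
        labels = pd.Series([cols[i] for i in idx], index=features.index, dtype=object)
        post = pd.DataFrame(proba, index=features.index, columns=cols)
        return labels, post


def train_node(
    node_id: str,
    labeled_features: pd.DataFrame,
    seed: int = 0,
    feature_subset: list[str] | None = None,
    label_column: str = "label",
    n_estimators: int = 150,
    holdout_fraction: float = 0.25,
) -> GatingNode:
    """Fit one gating node on a labeled feature table.

    Requires >= 20 examples of every node class; records stratified
    held-out accuracy in ``training_meta`` then refits on all rows.
    Identical inputs and seed give identical fitted predictions.
    """
    if node_id not in CLASS_ORDERS:
        raise GatingError(f"unknown node {node_id!r}")
    classes = CLASS_ORDERS[node_id]
    features = feature_subset or NODE_FEATURES[node_id]
    labels = labeled_features[label_column]
    extra = set(labels.unique()) - set(classes)
    if extra:
        raise GatingError(f"labels {sorted(extra)} not in node classes {classes}")
    counts = labels.value_counts()
    missing = [c for c in classes if counts.get(c, 0) < 20]
    if missing:
        raise GatingError(
            f"node {node_id}: need >= 20 examples per class, short for {missing} "
            f"(classes: {classes})"
        )
    missing_feats = [f for f in features if f not in labeled_features.columns]
    if missing_feats:
        raise GatingError(f"node {node_id}: missing feature columns {missing_feats}")

    X = labeled_features[features].to_numpy(dtype=float)
    y = labels.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    probe = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    probe.fit(X_tr, y_tr)
    holdout_acc = float(accuracy_score(y_te, probe.predict(X_te)))

    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X, y)
    meta = {
        "n_per_class": counts.to_dict(),
        "seed": seed,
        "holdout_accuracy": holdout_acc,
        "classifier": "RandomForestClassifier",
        "n_estimators": n_estimators,
    }
    return GatingNode(node_id, classes, list(features), model, meta)


# ---------------------------------------------------------------------------
# rule-based fallback gates
# ---------------------------------------------------------------------------

def hio_rule(
    features: pd.DataFrame,
    reference_median: float | None = None,
    thresholds: RuleThresholds | None = None,
) -> pd.Series:
    """High-intensity-object rule: mean Hoechst above k x the median
    nuclear mean (reference from DMSO wells when available), or
    non-nuclear shape with moderately elevated intensity."""
    t = thresholds or RuleThresholds()
    med = reference_median if reference_median is not None else float(
        features["hoechst_mean"].median()
    )
    if med <= 0:
        med = 1.0
    bright = features["hoechst_mean"] > t.hio_intensity_k * med
    misshapen = (features["nucleus_solidity"] < t.hio_min_solidity) & (
        features["hoechst_mean"] > t.hio_shape_k * med
    )
    out = pd.Series("normal", index=features.index, dtype=object)
    out[bright | misshapen] = "high_intensity_object"
    return out


def annexin_rule(features: pd.DataFrame, thresholds: RuleThresholds | None = None) -> pd.Series:
    t = thresholds or RuleThresholds()
    pos = features["ring_annexin_mean"] > t.annexin_positive
    return pd.Series(np.where(pos, "apoptotic", "mitotic"), index=features.index, dtype=object)


def fucci_rule(features: pd.DataFrame, thresholds: RuleThresholds | None = None) -> pd.Series:
    t = thresholds or RuleThresholds()
    red = features["nuc561_mean"] > t.fucci_red
    green = features["nuc488_mean"] > t.fucci_green
    out = pd.Series("unlabeled", index=features.index, dtype=object)
    out[red & ~green] = "red"
    out[green & ~red] = "green"
    out[red & green] = "yellow"
    return out


def annexin_positive(features: pd.DataFrame, thresholds: RuleThresholds | None = None) -> pd.Series:
    t = thresholds or RuleThresholds()
    return features["ring_annexin_mean"] > t.annexin_positive


# ---------------------------------------------------------------------------
# node-level operations with hierarchy enforcement
# ---------------------------------------------------------------------------

def classify_hio(
    features: pd.DataFrame,
    node: GatingNode | None = None,
    reference_median: float | None = None,
    thresholds: RuleThresholds | None = None,
) -> pd.Series:
    if node is not None:
        labels, _ = node.predict(features)
        return labels
    return hio_rule(features, reference_median, thresholds)


def classify_nuclei(
    node: GatingNode,
    features: pd.DataFrame,
    hio_labels: pd.Series | None = None,
) -> pd.Series:
    if node is None:
        raise GatingError("NUCLEI3 node is untrained and has no rule fallback")
    if hio_labels is not None and (hio_labels.loc[features.index] == "high_intensity_object").any():
        raise HierarchyError("NUCLEI3 received high-intensity objects")
    labels, _ = node.predict(features)
    return labels


def resolve_pyknosed(
    features: pd.DataFrame,
    nuclei_labels: pd.Series,
    node: GatingNode | None = None,
    thresholds: RuleThresholds | None = None,
) -> pd.Series:
    bad = nuclei_labels.loc[features.index] != "pyknosed"
    if bad.any():
        raise HierarchyError(
            f"PYKNOSED2 received {int(bad.sum())} non-pyknosed cells"
        )
    if "ring_annexin_mean" not in features.columns:
        raise GatingError("PYKNOSED2 requires the Annexin ring feature")
    if node is not None:
        labels, _ = node.predict(features)
        return labels
    return annexin_rule(features, thresholds)


def classify_viability(node: GatingNode, features: pd.DataFrame) -> pd.Series:
    if node is None:
        raise GatingError("VIA5 node is untrained; train it before classifying viability")
    labels, _ = node.predict(features)
    return labels


def classify_phenotypes(
    features: pd.DataFrame,
    nuclei_labels: pd.Series,
    tubulin: GatingNode,
    mito: GatingNode,
    membrane: GatingNode,
    thresholds: RuleThresholds | None = None,
) -> pd.DataFrame:
    """Three independent binary phenotype labels for healthy-nucleus
    cells; the mito decision is ``not_evaluated`` in Annexin-positive
    cells."""
    bad = nuclei_labels.loc[features.index] != "healthy"
    if bad.any():
        raise HierarchyError(
            f"phenotype nodes received {int(bad.sum())} non-healthy-nucleus cells"
        )
    out = pd.DataFrame(index=features.index)
    out["label_tubulin"], _ = tubulin.predict(features)
    out["label_membrane"], _ = membrane.predict(features)
    ann_pos = annexin_positive(features, thresholds)
    mito_labels, _ = mito.predict(features)
    out["label_mito"] = mito_labels.where(~ann_pos, other="not_evaluated")
    return out


def classify_fucci(
    features: pd.DataFrame,
    nuclei_labels: pd.Series,
    node: GatingNode | None = None,
    thresholds: RuleThresholds | None = None,
    allowed_nuclei: Iterable[str] = ("healthy",),
) -> pd.Series:
    for col in ("nuc488_mean", "nuc561_mean"):
        if col not in features.columns:
            raise GatingError(f"FUCCI gating requires feature {col!r} (FUCCI channels missing)")
    bad = ~nuclei_labels.loc[features.index].isin(list(allowed_nuclei))
    if bad.any():
        raise HierarchyError(
            f"FUCCI node received {int(bad.sum())} cells outside {list(allowed_nuclei)}"
        )
    if node is not None:
        labels, _ = node.predict(features)
        return labels
    return fucci_rule(features, thresholds)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

@dataclass
class GatingModel:
    """Node set + thresholds for one analysis mode, applied as a tree."""

    mode: str
    nodes: dict[str, GatingNode] = dc_field(default_factory=dict)
    thresholds: RuleThresholds = dc_field(default_factory=RuleThresholds)
    version: str = "1"
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODE_NODES:
            raise GatingError(f"bad mode {self.mode!r}")
        allowed = set(MODE_NODES[self.mode])
        bad = set(self.nodes) - allowed
        if bad:
            raise GatingError(f"nodes {sorted(bad)} not valid for mode {self.mode!r}")

    def apply(
        self,
        features: pd.DataFrame,
        reference_median: float | None = None,
    ) -> tuple[pd.DataFrame, dict]:
        """Gate every cell through the mode's tree.

        Returns a label table (one row per input cell; NaN where a node's
        input filter excluded the cell) and an audit dict with counts
        entering / classified / filtered per node.
        """
        out = pd.DataFrame(index=features.index)
        audit: dict[str, dict] = {}
        n = len(features)

        def posterior(node_id: str, rows) -> pd.Series | None:
            node = self.nodes.get(node_id)
            if node is None or not len(rows):
                return None
            _, post = node.predict(rows)
            return post.max(axis=1)

        hio = classify_hio(features, self.nodes.get("HIO"), reference_median, self.thresholds)
        out["label_hio"] = hio
        audit["HIO"] = {"entering": n, "classified": n, "filtered": 0}

        normal = features.index[hio == "normal"]
        audit["NUCLEI3"] = {
            "entering": n, "classified": len(normal), "filtered": n - len(normal)
        }
        out["label_nuclei"] = pd.Series(np.nan, index=features.index, dtype=object)
        if len(normal) and "NUCLEI3" in self.nodes:
            out.loc[normal, "label_nuclei"] = classify_nuclei(
                self.nodes["NUCLEI3"], features.loc[normal], hio
            )
            p = posterior("NUCLEI3", features.loc[normal])
            if p is not None:
                out.loc[normal, "p_nuclei"] = p
        nuclei = out["label_nuclei"]

        if "PYKNOSED2" in MODE_NODES[self.mode]:
            pyk = features.index[nuclei == "pyknosed"]
            audit["PYKNOSED2"] = {
                "entering": len(normal),
                "classified": len(pyk),
                "filtered": len(normal) - len(pyk),
            }
            out["label_pyknosed"] = pd.Series(np.nan, index=features.index, dtype=object)
            if len(pyk):
                out.loc[pyk, "label_pyknosed"] = resolve_pyknosed(
                    features.loc[pyk], nuclei, self.nodes.get("PYKNOSED2"), self.thresholds
                )

        if self.mode == "viability" and "VIA5" in self.nodes:
            audit["VIA5"] = {
                "entering": n, "classified": len(normal), "filtered": n - len(normal)
            }
            out["label_via"] = pd.Series(np.nan, index=features.index, dtype=object)
            if len(normal):
                out.loc[normal, "label_via"] = classify_viability(
                    self.nodes["VIA5"], features.loc[normal]
                )
                p = posterior("VIA5", features.loc[normal])
                if p is not None:
                    out.loc[normal, "p_via"] = p

        if self.mode == "multiplex" and all(
            k in self.nodes for k in ("TUBULIN", "MITO", "MEMBRANE")
        ):
            healthy = features.index[nuclei == "healthy"]
            for node_id in ("TUBULIN", "MITO", "MEMBRANE"):
                audit[node_id] = {
                    "entering": len(normal),
                    "classified": len(healthy),
                    "filtered": len(normal) - len(healthy),
                }
            for col in ("label_tubulin", "label_mito", "label_membrane"):
                out[col] = pd.Series(np.nan, index=features.index, dtype=object)
            if len(healthy):
                pheno = classify_phenotypes(
                    features.loc[healthy], nuclei,
                    self.nodes["TUBULIN"], self.nodes["MITO"], self.nodes["MEMBRANE"],
                    self.thresholds,
                )
                out.loc[healthy, ["label_tubulin", "label_mito", "label_membrane"]] = pheno

        if self.mode == "fucci":
            healthy = features.index[nuclei == "healthy"]
            audit["FUCCI"] = {
                "entering": len(normal),
                "classified": len(healthy),
                "filtered": len(normal) - len(healthy),
            }
            out["label_fucci"] = pd.Series(np.nan, index=features.index, dtype=object)
            if len(healthy):
                out.loc[healthy, "label_fucci"] = classify_fucci(
                    features.loc[healthy], nuclei, self.nodes.get("FUCCI"), self.thresholds
                )

        return out, audit

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "GatingModel":
        model = joblib.load(path)
        if not isinstance(model, GatingModel):
            raise GatingError(f"{path} does not contain a GatingModel")
        return model
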