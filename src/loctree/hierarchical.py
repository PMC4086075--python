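"""Hierarchical SVM tree for de novo localization prediction.

A binary decision tree mirrors the cell's sorting pathways: the root
separates secretory-pathway classes from the rest, deeper nodes split
membrane from soluble compartments, and every leaf is one localization
class.  Each internal node holds a soft-margin SVM trained on the profile
kernel (precomputed Gram matrix) plus a Platt sigmoid calibrating its
decision values into probabilities.  A query descends from the root, taking
at each node the side whose calibrated probability is at least 0.5; the
reliability index is 100 times the product of the per-step confidences,
rounded — so a depth-d path can never score below 100 * 0.5^d.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC

from loctree.classes import DomainOfLife, class_set
from loctree.errors import FormatError, ValidationError
from loctree.profile_kernel import (
    KernelParams,
    KmerFeatureVector,
    feature_map,
    features_to_csr,
    kernel_matrix_from_features,
)
from loctree.records import (
    AnnotationDB,
    Prediction,
    PredictionSource,
    SequenceProfile,
)

__all__ = [
    "NodeModel",
    "TreeModel",
    "TreeSpec",
    "default_tree_spec",
    "load_model",
    "load_tree_spec",
    "predict_de_novo",
    "ri_from_confidences",
    "save_model",
    "train_node",
    "train_tree",
]


@dataclass(frozen=True)
class TreeSpec:
    """Topology of the decision tree.

    ``nodes`` maps an internal node id to its (left, right) children; a
    child is either another internal node id or a leaf class label.  The
    leaf set must equal the domain's class set exactly.
    """

    domain_of_life: DomainOfLife
    root_id: str
    nodes: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        classes = set(class_set(self.domain_of_life))
        if self.root_id not in self.nodes:
            raise ValidationError(f"root {self.root_id!r} is not an internal node")
        internal = set(self.nodes)
        if internal & classes:
            raise ValidationError("internal node ids collide with class labels")
        # walk from the root: every internal node reachable exactly once
        leaves: list[str] = []
        seen: set[str] = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValidationError(f"node {nid!r} reachable more than once")
            seen.add(nid)
            children = self.nodes[nid]
            if len(children) != 2:
                raise ValidationError(f"node {nid!r} is not binary")
            for child in children:
                if child in self.nodes:
                    stack.append(child)
                else:
                    leaves.append(child)
        if seen != internal:
            raise ValidationError(
                f"unreachable internal nodes: {sorted(internal - seen)}")
        if len(leaves) != len(set(leaves)):
            raise ValidationError("duplicate leaf labels")
        if set(leaves) != classes:
            missing = classes - set(leaves)
            extra = set(leaves) - classes
            raise ValidationError(
                f"leaf set does not match the {self.domain_of_life.value} "
                f"class set (missing {sorted(missing)}, extra {sorted(extra)})")

    def is_leaf(self, child: str) -> bool:
        return child not in self.nodes

    def leaves_under(self, child: str) -> frozenset[str]:
        """All leaf labels in the subtree rooted at *child*."""
        if self.is_leaf(child):
            return frozenset([child])
        out: set[str] = set()
        stack = [child]
        while stack:
            nid = stack.pop()
            for c in self.nodes[nid]:
                if self.is_leaf(c):
                    out.add(c)
                else:
                    stack.append(c)
        return frozenset(out)

    @property
    def internal_ids(self) -> list[str]:
        return list(self.nodes)


@dataclass
class NodeModel:
    """Trained SVM + Platt calibration at one internal node.

    The decision value for a query feature vector q is
    ``f = sum_i dual_coefs[i] * K(q, support_i) + bias``; the probability of
    the positive side is ``1 / (1 + exp(platt_a * f + platt_b))`` with
    ``platt_a < 0``, so larger decision values mean more confidence toward
    the positive child.
    """

    node_id: str
    support_ids: list[str]
    dual_coefs: list[float]
    bias: float
    platt_a: float
    platt_b: float
    pos_child: str
    neg_child: str

    def __post_init__(self) -> None:
        if not self.support_ids:
            raise ValidationError(f"node {self.node_id}: no support examples")
        if len(self.support_ids) != len(self.dual_coefs):
            raise ValidationError(f"node {self.node_id}: support/coef mismatch")
        if self.platt_a >= 0:
            raise ValidationError(f"node {self.node_id}: platt_a must be < 0")

    def positive_probability(self, decision_value: float) -> float:
        z = self.platt_a * decision_value + self.platt_b
        if z >= 0:
            return math.exp(-z) / (1.0 + math.exp(-z))
        return 1.0 / (1.0 + math.exp(z))


@dataclass
class TreeModel:
    """A trained tree: topology, kernel parameters, node SVMs, and the
    training feature vectors the node SVMs refer to."""

    spec: TreeSpec
    params: KernelParams
    node_models: dict[str, NodeModel]
    training_features: dict[str, KmerFeatureVector]
    C: float = 1.0
    _index: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = set(self.spec.internal_ids) - set(self.node_models)
        if missing:
            raise ValidationError(f"internal nodes without models: {sorted(missing)}")
        for nm in self.node_models.values():
            for sid in nm.support_ids:
                if sid not in self.training_features:
                    raise ValidationError(
                        f"node {nm.node_id}: support id {sid!r} has no features")

    def _ensure_index(self):
        # cached normalized CSR over the training features, for fast kernel rows
        if self._index is None:
            ids = sorted(self.training_features)
            vectors = [self.training_features[i] for i in ids]
            matrix, vocab = features_to_csr(vectors)
            row_of = {pid: i for i, pid in enumerate(ids)}
            self._index = (row_of, matrix, vocab)
        return self._index

    def kernel_row(self, query: KmerFeatureVector) -> dict[str, float]:
        """Normalized kernel of *query* against every training example."""
        if len(query) == 0:
            raise ValidationError("kernel undefined for an empty feature vector")
        row_of, matrix, vocab = self._ensure_index()
        cols = np.searchsorted(vocab, query.codes)
        valid = cols < len(vocab)
        if np.any(valid):
            valid &= vocab[np.minimum(cols, len(vocab) - 1)] == query.codes
        qvec = np.zeros(len(vocab))
        qvec[cols[valid]] = query.count_values[valid].astype(float) / query.norm
        krow = matrix @ qvec
        return {pid: float(krow[i]) for pid, i in row_of.items()}


def ri_from_confidences(confidences: list[float]) -> int:
    """Reliability index: round(100 * product of decision-path confidences)."""
    if not confidences:
        raise ValidationError("empty decision path")
    product = 1.0
    for c in confidences:
        product *= c
    return int(round(100.0 * product))


def _fit_platt(decision_values: np.ndarray, labels: np.ndarray,
               max_iter: int = 100) -> tuple[float, float]:
    """Platt sigmoid fit with Laplace-smoothed targets (Newton + backtracking).

    Fits (a, b) of p(+1 | f) = 1 / (1 + exp(a f + b)) on the training
    decision values; deterministic, no inner cross-validation.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    prior1 = int(np.sum(y > 0))
    prior0 = len(y) - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y > 0, hi, lo)
    min_step, sigma = 1e-10, 1e-12
    a, b = 0.0, math.log((prior0 + 1.0) / (prior1 + 1.0))

    def objective(a_: float, b_: float) -> float:
        fab = a_ * f + b_
        return float(np.sum(np.where(
            fab >= 0,
            t * fab + np.log1p(np.exp(-np.abs(fab))),
            (t - 1.0) * fab + np.log1p(np.exp(-np.abs(fab))),
        )))

    best = objective(a, b)
    for _ in range(max_iter):
        fab = a * f + b
        p = np.where(fab >= 0,
                     np.exp(-np.clip(fab, 0, None)) / (1 + np.exp(-np.clip(fab, 0, None))),
                     1.0 / (1 + np.exp(np.clip(fab, None, 0))))
        d1 = t - p
        d2 = p * (1.0 - p)
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= min_step:
            na, nb = a + step * da, b + step * db
            nf = objective(na, nb)
            if nf < best + 1e-4 * step * gd:
                a, b, best = na, nb, nf
                break
            step /= 2.0
        else:
            break
    return a, b


def train_node(kmatrix: np.ndarray, labels: np.ndarray, C: float = 1.0,
               *, node_id: str = "node", support_ids: list[str] | None = None,
               pos_child: str = "+", neg_child: str = "-") -> NodeModel:
    """Train one binary SVM node on a precomputed kernel submatrix.

    Labels are +/-1; +1 examples belong to the positive child's subtree.
    After the SVM fit, a Platt sigmoid is fitted to the training decision
    values.
    """
    labels = np.asarray(labels)
    kmatrix = np.asarray(kmatrix, dtype=float)
    if not np.all(np.isfinite(kmatrix)):
        raise ValidationError(f"node {node_id}: non-finite kernel entries")
    if len(set(labels.tolist())) < 2:
        raise ValidationError(f"node {node_id}: training labels single-class")
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(kmatrix, labels)
    decision = clf.decision_function(kmatrix)
    a, b = _fit_platt(decision, labels)
    a = min(a, -1e-8)  # degenerate flat fits clamp to a barely-negative slope
    support = clf.support_
    ids = (support_ids if support_ids is not None
           else [str(i) for i in range(len(labels))])
    return NodeModel(
        node_id=node_id,
        support_ids=[ids[i] for i in support],
        dual_coefs=[float(c) for c in clf.dual_coef_[0]],
        bias=float(clf.intercept_[0]),
        platt_a=float(a),
        platt_b=float(b),
        pos_child=pos_child,
        neg_child=neg_child,
    )


def train_tree(profiles: list[SequenceProfile], annotations: AnnotationDB,
               spec: TreeSpec, params: KernelParams, C: float = 1.0) -> TreeModel:
    """Train every internal node of *spec* on the annotated profiles.

    Each node is trained independently on the examples whose class lies in
    its subtree; the binary label says which child subtree holds the class
    (+1 = left).  Every class needs at least two examples.
    """
    classes = set(class_set(spec.domain_of_life))
    ids, labels_by_id = [], {}
    for p in profiles:
        cls = annotations.get(p.id)
        if cls is None:
            raise ValidationError(f"{p.id}: no annotation for training example")
        if cls not in classes:
            raise ValidationError(f"{p.id}: class {cls!r} outside the tree's domain")
        ids.append(p.id)
        labels_by_id[p.id] = cls
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate profile ids in training set")
    counts: dict[str, int] = {}
    for cls in labels_by_id.values():
        counts[cls] = counts.get(cls, 0) + 1
    thin = sorted(c for c in classes if counts.get(c, 0) < 2)
    if thin:
        raise ValidationError(f"classes with < 2 training examples: {thin}")

    vectors = [feature_map(p, params) for p in profiles]
    features = dict(zip(ids, vectors))
    gram = kernel_matrix_from_features(vectors)

    node_models: dict[str, NodeModel] = {}
    for nid in spec.internal_ids:
        left, right = spec.nodes[nid]
        left_classes = spec.leaves_under(left)
        right_classes = spec.leaves_under(right)
        member_idx = [i for i, pid in enumerate(ids)
                      if labels_by_id[pid] in left_classes
                      or labels_by_id[pid] in right_classes]
        sub_labels = np.array([
            1 if labels_by_id[ids[i]] in left_classes else -1
            for i in member_idx])
        sub_k = gram[np.ix_(member_idx, member_idx)]
        node_models[nid] = train_node(
            sub_k, sub_labels, C,
            node_id=nid,
            support_ids=[ids[i] for i in member_idx],
            pos_child=left, neg_child=right,
        )
    return TreeModel(spec, params, node_models, features, C=C)


def predict_de_novo(profile: SequenceProfile, model: TreeModel) -> Prediction:
    """Descend the SVM tree from the root; RI is the path-confidence product.

    At each node the Platt probability p of the positive child is computed
    from the decision value; the walk takes the positive child when
    p >= 0.5 (ties included) and records max(p, 1-p) as the step confidence.
    """
    query = feature_map(profile, model.params)
    krow = model.kernel_row(query)
    path: list[tuple[str, str, float]] = []
    node_id = model.spec.root_id
    while True:
        nm = model.node_models[node_id]
        f = sum(c * krow[sid] for c, sid in zip(nm.dual_coefs, nm.support_ids))
        f += nm.bias
        p = nm.positive_probability(f)
        if p >= 0.5:
            side, child, conf = "pos", nm.pos_child, p
        else:
            side, child, conf = "neg", nm.neg_child, 1.0 - p
        path.append((node_id, side, conf))
        if model.spec.is_leaf(child):
            return Prediction(
                id=profile.id,
                loc_class=child,
                ri=ri_from_confidences([c for _, _, c in path]),
                source=PredictionSource.DE_NOVO,
                path=path,
            )
        node_id = child


# ---------------------------------------------------------------------------
# serialization

def _spec_to_dict(spec: TreeSpec) -> dict:
    return {
        "domain": spec.domain_of_life.value,
        "root": spec.root_id,
        "nodes": {nid: list(children) for nid, children in spec.nodes.items()},
    }


def _spec_from_dict(payload: dict) -> TreeSpec:
    try:
        return TreeSpec(
            domain_of_life=DomainOfLife.from_string(payload["domain"]),
            root_id=payload["root"],
            nodes={nid: (c[0], c[1]) for nid, c in payload["nodes"].items()},
        )
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"malformed tree spec: {exc}") from exc


def load_tree_spec(path: str | os.PathLike) -> TreeSpec:
    """Load and validate a tree topology from its JSON config layout:
    ``{"domain": ..., "root": ..., "nodes": {id: [left, right], ...}}``."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    return _spec_from_dict(payload)


def default_tree_spec(domain: DomainOfLife) -> TreeSpec:
    """The shipped default topology for *domain* (an editable config file).

    The shapes follow the cell's sorting pathways — secretory-pathway split
    first, then membrane/soluble splits — with the correct leaf sets; they
    are a design choice of this package, not recovered tree weights.
    """
    ref = resources.files("loctree.data") / f"tree_{domain.value}.json"
    return _spec_from_dict(json.loads(ref.read_text()))


def save_model(model: TreeModel, path: str | os.PathLike) -> None:
    payload = {
        "format": "loctree-tree-model",
        "version": 1,
        "spec": _spec_to_dict(model.spec),
        "params": {"k": model.params.k, "theta": model.params.theta,
                   "alphabet": model.params.alphabet},
        "C": model.C,
        "nodes": {
            nid: {
                "support_ids": nm.support_ids,
                "dual_coefs": nm.dual_coefs,
                "bias": nm.bias,
                "platt_a": nm.platt_a,
                "platt_b": nm.platt_b,
                "pos_child": nm.pos_child,
                "neg_child": nm.neg_child,
            }
            for nid, nm in sorted(model.node_models.items())
        },
        "training_features": {
            pid: {"k": fv.k,
                  "codes": [int(c) for c in fv.codes],
                  "counts": [int(c) for c in fv.count_values]}
            for pid, fv in sorted(model.training_features.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path: str | os.PathLike) -> TreeModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if payload.get("format") != "loctree-tree-model":
        raise FormatError(f"{path}: not a tree-model file")
    spec = _spec_from_dict(payload["spec"])
    pp = payload["params"]
    params = KernelParams(k=pp["k"], theta=pp["theta"], alphabet=pp["alphabet"])
    nodes = {
        nid: NodeModel(node_id=nid, **nd)
        for nid, nd in payload["nodes"].items()
    }
    features = {
        pid: KmerFeatureVector(
            fv["k"], np.array(fv["codes"], np.int64),
            np.array(fv["counts"], np.int64))
        for pid, fv in payload["training_features"].items()
    }
    return TreeModel(spec, params, nodes, features, C=payload.get("C", 1.0))
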