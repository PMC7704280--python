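"""Sequential decision-tree data synthesis.

Variables are synthesized one at a time along a chosen sequence; each
variable is modelled by a tree fitted on the real data with all earlier
variables in the sequence as predictors, and a synthetic value is produced
by routing the partially synthesized record down the fitted tree and
sampling uniformly (with replacement) from the real values that fell in
the predicted terminal node.  For the sequence A→E→C→B→D this is:

    sample A' from the empirical distribution of A
    fit  F1: E ~ A            synthesize E' = F1(A')
    fit  F2: C ~ A + E        synthesize C' = F2(A', E')
    fit  F3: B ~ A + E + C    synthesize B' = F3(A', E', C')
    fit  F4: D ~ A + E + C + B  synthesize D' = F4(A', E', C', B')

The generator holds the fitted models and the first variable's marginal;
it can produce synthetic samples of any size.  Because terminal nodes pool
at least ``min_leaf`` training records, the leaf size acts as a privacy /
overfitting dial: leaves of size one on near-unique data reproduce real
records, large leaves blur them.

Trees are binary CART partitions (scikit-learn); the synthesis contract —
partition the predictor space, sample from the node — is agnostic to the
specific tree algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_model import Dataset, KIND_CONTINUOUS, VariableMeta


@dataclass
class _VariableModel:
    """Fitted tree for one position in the sequence, plus its leaf pools."""

    name: str
    predictors: list[str]
    tree: object  # fitted sklearn tree
    leaf_values: dict[int, np.ndarray]  # leaf id -> training target values


@dataclass
class _Encoder:
    """Ordinal encoding of categorical predictors, with modal fallback.

    A category never seen in training (possible when a synthetic value was
    produced by a different upstream node) is encoded as the modal training
    category, which routes it along the majority path of the tree.
    """

    categories: dict[str, dict] = field(default_factory=dict)
    modal: dict[str, object] = field(default_factory=dict)

    def fit(self, name: str, col: pd.Series) -> np.ndarray:
        cats = pd.Series(col.astype(str))
        order = sorted(cats.unique())
        self.categories[name] = {c: i for i, c in enumerate(order)}
        self.modal[name] = cats.mode(dropna=False).iloc[0]
        return self.transform(name, col)

    def transform(self, name: str, col: pd.Series) -> np.ndarray:
        table = self.categories[name]
        fallback = table[self.modal[name]]
        return col.astype(str).map(lambda v: table.get(v, fallback)).to_numpy(dtype=float)


@dataclass
class SequentialGenerator:
    sequence: list[str]
    meta: list[VariableMeta]
    first_marginal: np.ndarray  # observed values of the first variable
    models: list[_VariableModel]
    encoder: _Encoder
    min_leaf: int
    max_depth: int | None

    def generate(self, m: int, rng: np.random.Generator | None = None,
                 seed: int | None = None) -> Dataset:
        """Draw a fully synthetic sample of m records."""
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(seed or 0)
        out: dict[str, np.ndarray] = {}
        first = self.sequence[0]
        out[first] = rng.choice(self.first_marginal, size=m, replace=True)
        for vm in self.models:
            X = np.column_stack([
                self._encode_col(p, pd.Series(out[p])) for p in vm.predictors
            ])
            leaves = vm.tree.apply(X)
            vals = np.empty(m, dtype=object)
            for leaf in np.unique(leaves):
                pool = vm.leaf_values[int(leaf)]
                idx = leaves == leaf
                vals[idx] = rng.choice(pool, size=int(idx.sum()), replace=True)
            out[vm.name] = vals
        df = pd.DataFrame({m_.name: pd.Series(out[m_.name]) for m_ in self.meta
                           if m_.name in out})
        for m_ in self.meta:
            if m_.name in df.columns and m_.kind == KIND_CONTINUOUS:
                df[m_.name] = pd.to_numeric(df[m_.name])
        used_meta = [m_ for m_ in self.meta if m_.name in df.columns]
        return Dataset(df, used_meta, "synthetic_sample")

    def _encode_col(self, name: str, col: pd.Series) -> np.ndarray:
        meta = next(m for m in self.meta if m.name == name)
        if meta.kind == KIND_CONTINUOUS:
            return pd.to_numeric(col).to_numpy(dtype=float)
        return self.encoder.transform(name, col)


def fit(
    real: Dataset,
    sequence: list[str] | None = None,
    min_leaf: int = 5,
    max_depth: int | None = None,
) -> SequentialGenerator:
    """Fit the sequential generator on a real sample.

    ``sequence`` defaults to the dataset's column order.  Classification
    trees are used for nominal/binary targets and regression trees for
    continuous targets; both stop splitting at ``min_leaf`` training
    records per node, so every terminal pool holds at least ``min_leaf``
    values.
    """
    sequence = list(sequence or [m.name for m in real.meta])
    names = {m.name for m in real.meta}
    if set(sequence) - names:
        raise ValueError(f"sequence names unknown variables: {set(sequence) - names}")
    if real.n < min_leaf:
        raise ValueError(f"need at least min_leaf={min_leaf} records to fit")

    enc = _Encoder()
    encoded: dict[str, np.ndarray] = {}
    for nm in sequence:
        meta = real.meta_for(nm)
        col = real.records[nm]
        if meta.kind == KIND_CONTINUOUS:
            encoded[nm] = pd.to_numeric(col).to_numpy(dtype=float)
        else:
            encoded[nm] = enc.fit(nm, col)

    first = sequence[0]
    first_marginal = real.records[first].to_numpy()
    models: list[_VariableModel] = []
    for pos in range(1, len(sequence)):
        target = sequence[pos]
        predictors = sequence[:pos]
        meta = real.meta_for(target)
        X = np.column_stack([encoded[p] for p in predictors])
        y_raw = real.records[target].to_numpy()
        if meta.kind == KIND_CONTINUOUS:
            tree = DecisionTreeRegressor(min_samples_leaf=min_leaf, max_depth=max_depth,
                                         random_state=0)
            tree.fit(X, pd.to_numeric(real.records[target]).to_numpy(dtype=float))
        else:
            tree = DecisionTreeClassifier(min_samples_leaf=min_leaf, max_depth=max_depth,
                                          random_state=0)
            tree.fit(X, real.records[target].astype(str).to_numpy())
        leaves = tree.apply(X)
        leaf_values = {int(l): y_raw[leaves == l] for l in np.unique(leaves)}
        models.append(_VariableModel(target, predictors, tree, leaf_values))
    return SequentialGenerator(
        sequence=sequence,
        meta=[real.meta_for(nm) for nm in sequence],
        first_marginal=first_marginal,
        models=models,
        encoder=enc,
        min_leaf=min_leaf,
        max_depth=max_depth,
    )


def synthesize(
    real: Dataset,
    m: int | None = None,
    sequence: list[str] | None = None,
    min_leaf: int = 5,
    max_depth: int | None = None,
    seed: int = 0,
) -> Dataset:
    """Fit and generate in one call; m defaults to the real sample size."""
    gen = fit(real, sequence=sequence, min_leaf=min_leaf, max_depth=max_depth)
    return gen.generate(m or real.n, rng=np.random.default_rng(seed))
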