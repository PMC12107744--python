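"""Typed containers and on-disk formats for expression data, condition labels and GRNs.

The tool works on a normalized expression matrix (genes x samples), a
two-level condition annotation of the samples, and -- for pathway-level
analysis (mode 2) -- a directed regulator->target edge list in the usual
two-column TF/TG layout.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum recommended number of samples per condition; below this the
#: permutation null becomes coarse and a warning is emitted.
MIN_RECOMMENDED_SAMPLES = 10


class DataError(ValueError):
    """Raised when an input file or container violates the data contract."""


@dataclass
class ExpressionDataset:
    """A normalized expression matrix with optional two-level condition labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (opaque strings), one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Expression matrix of shape ``(n_genes, n_samples)``; all finite.
    condition_of
        Mapping ``sample_id -> condition label``. When present it must cover
        every sample and use exactly two distinct labels.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise DataError(f"duplicate gene identifiers: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise DataError(f"duplicate sample identifiers: {sorted(dup_s)}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}
        if self.condition_of:
            self._validate_conditions()

    def _validate_conditions(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise DataError(f"samples without a condition label: {missing}")
        extra = [s for s in self.condition_of if s not in self._sample_index]
        if extra:
            raise DataError(f"condition table samples absent from dataset: {extra}")
        labels = sorted(set(self.condition_of.values()))
        if len(labels) != 2:
            raise DataError(
                f"expected exactly two conditions, found {len(labels)}: {labels}"
            )
        for lab in labels:
            n = sum(1 for v in self.condition_of.values() if v == lab)
            if n < 2:
                raise DataError(f"condition {lab!r} has {n} sample(s); need >= 2")
            if n < MIN_RECOMMENDED_SAMPLES:
                warnings.warn(
                    f"condition {lab!r} has only {n} samples; at least around "
                    f"{MIN_RECOMMENDED_SAMPLES} samples per condition are "
                    "recommended for a stable permutation background",
                    UserWarning,
                    stacklevel=3,
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def condition_labels(self) -> tuple[str, str]:
        """The two condition labels in sorted order (A, B)."""
        labels = sorted(set(self.condition_of.values()))
        if len(labels) != 2:
            raise DataError("dataset has no two-level condition annotation")
        return labels[0], labels[1]

    def sample_mask(self, condition: str) -> np.ndarray:
        """Boolean column mask selecting the samples of one condition."""
        return np.array(
            [self.condition_of.get(s) == condition for s in self.sample_ids]
        )

    def expression_of(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise DataError(f"gene {gene_id!r} not in dataset") from None

    def with_conditions(self, condition_of: Mapping[str, str]) -> "ExpressionDataset":
        """Return a copy of this dataset carrying the given condition labels."""
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            condition_of=dict(condition_of),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographic (min, max) ordering of an unordered gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class CandidateEdgeSet:
    """The gene pairs submitted to differential testing.

    Mode 1 tests every unordered gene pair (undirected differential
    co-expression); mode 2 tests only a user-supplied directed TF->TG list
    (pathway-level analysis).
    """

    mode: int
    edges: list[tuple[str, str]]
    directed: bool

    def __post_init__(self) -> None:
        if self.mode not in (1, 2):
            raise DataError(f"mode must be 1 or 2, got {self.mode}")
        if self.mode == 1 and self.directed:
            raise DataError("mode 1 edge sets are undirected")
        for s, t in self.edges:
            if s == t:
                raise DataError(f"self-pair {s!r} not allowed")
        key = (lambda e: e) if self.directed else (lambda e: canonical_pair(*e))
        seen = set()
        for e in self.edges:
            k = key(e)
            if k in seen:
                raise DataError(f"duplicate edge {e}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.edges)

    def canonical(self, edge: tuple[str, str]) -> tuple[str, str]:
        """Comparison form of an edge: ordered pair if directed, else (min, max)."""
        return tuple(edge) if self.directed else canonical_pair(*edge)

    @classmethod
    def all_pairs(cls, dataset: ExpressionDataset) -> "CandidateEdgeSet":
        """Mode-1 candidate set: all G(G-1)/2 canonical unordered pairs."""
        genes = sorted(dataset.gene_ids)
        edges = list(itertools.combinations(genes, 2))
        return cls(mode=1, edges=edges, directed=False)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], dataset: ExpressionDataset
    ) -> "CandidateEdgeSet":
        """Mode-2 candidate set: the provided directed TF->TG pairs, filtered
        to genes present in the dataset, with duplicates and self-loops dropped."""
        kept: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        n_in = 0
        for s, t in edges:
            n_in += 1
            s, t = str(s), str(t)
            if s == t or (s, t) in seen:
                continue
            if s not in dataset._gene_index or t not in dataset._gene_index:
                continue
            seen.add((s, t))
            kept.append((s, t))
        logger.info("GRN filter: kept %d of %d input edges", len(kept), n_in)
        if not kept:
            raise DataError(
                "no GRN edges overlap the dataset genes; nothing to test"
            )
        return cls(mode=2, edges=kept, directed=True)


# -- readers / writers -----------------------------------------------------


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a tab- or comma-separated text table (delimiter auto-detected)."""
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col,
                       dtype=str, keep_default_na=False, na_values=[""])


def read_expression(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionDataset:
    """Read a delimited expression matrix into an (unlabeled) dataset.

    The file has one header row and one identifier column.  With
    ``orientation="samples_in_rows"`` the on-disk table is transposed on
    ingestion; the in-memory layout is always genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "samples_in_rows":
        raw = raw.T
    dup = _duplicates(list(raw.index))
    if dup:
        raise DataError(f"duplicate gene identifiers in {path}: {sorted(dup)}")
    dup = _duplicates(list(raw.columns))
    if dup:
        raise DataError(f"duplicate sample identifiers in {path}: {sorted(dup)}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"missing value at gene {raw.index[i]!r}, sample "
            f"{raw.columns[j]!r} in {path}; the method defines no imputation"
        )
    return ExpressionDataset(
        gene_ids=list(raw.index),
        sample_ids=list(raw.columns),
        values=numeric.to_numpy(dtype=float),
    )


def read_conditions(path: str | Path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Attach condition labels from a two-column ``sample, condition`` table."""
    tab = _read_table(path)
    if tab.shape[1] < 2:
        raise DataError(f"condition table {path} needs columns sample, condition")
    cols = [c.lower() for c in tab.columns]
    s_col = tab.columns[cols.index("sample")] if "sample" in cols else tab.columns[0]
    c_col = (
        tab.columns[cols.index("condition")] if "condition" in cols else tab.columns[1]
    )
    condition_of = {str(r[s_col]): str(r[c_col]) for _, r in tab.iterrows()}
    return dataset.with_conditions(condition_of)


def read_grn(path: str | Path, dataset: ExpressionDataset) -> CandidateEdgeSet:
    """Read a TRRUST-style regulator/target table into a mode-2 candidate set.

    Extra columns beyond the first two are ignored.
    """
    tab = _read_table(path)
    if tab.shape[1] < 2:
        raise DataError(f"GRN table {path} needs at least two columns (tf, tg)")
    edges = [
        (str(r.iloc[0]), str(r.iloc[1])) for _, r in tab.iterrows()
    ]
    return CandidateEdgeSet.from_edges(edges, dataset)


#: Column order of the network output table.
NETWORK_COLUMNS = [
    "source", "target", "r_a", "r_b", "r_ab", "delta_r", "s",
    "p_delta_r", "p_s", "padj_delta_r", "padj_s",
    "sig_delta_r", "sig_s", "degenerate",
]


def write_network(network, path: str | Path, significant_only: bool = False) -> None:
    """Write a differential network as a TSV table, one row per tested edge.

    With ``significant_only`` the table is restricted to edges passing the
    network's significance rule (a header-only file is valid output).
    Row order follows the input edge order, so repeated runs with the same
    seed produce byte-identical files.
    """
    df = network.to_frame()
    if significant_only:
        df = df[network.significance_mask()]
    df.to_csv(path, sep="\t", index=False)


def read_network_table(path: str | Path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("sig_delta_r", "sig_s", "degenerate"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(bool)
    return df
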