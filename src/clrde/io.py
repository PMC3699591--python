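"""Count-table, design and result-table I/O.

All tabular formats are plain TSV: UTF-8, tab-separated, mandatory header
row, lines starting with ``#`` ignored.  Count tables have gene identifiers
in the first column and one sample per column; designs map sample to
condition, one pair per line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "DesignTwoGroup",
    "ValidationError",
    "read_counts",
    "read_design",
    "write_results",
    "read_results",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountTable:
    """Genes x samples matrix of non-negative integer read counts.

    Attributes
    ----------
    gene_ids : list of str
        Unique, non-empty gene identifiers (row labels).
    sample_ids : list of str
        Unique, non-empty sample identifiers (column labels).
    counts : ndarray of shape (D, S), integer
        Read counts; ``counts[g, s]`` is the count of gene g in sample s.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        d, s = self.counts.shape
        if len(self.gene_ids) != d or len(self.sample_ids) != s:
            raise ValidationError("counts shape does not match identifier lists")
        if d < 2:
            raise ValidationError(
                "at least two genes are required: the log-ratio transform is "
                "undefined for a single gene"
            )
        if len(set(self.gene_ids)) != d:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != s:
            raise ValidationError("duplicate sample identifiers")
        if any(not g for g in self.gene_ids) or any(not x for x in self.sample_ids):
            raise ValidationError("empty identifier")
        if not np.issubdtype(self.counts.dtype, np.integer):
            # reject silently-float input unless it is exactly integral
            if not np.all(np.isfinite(self.counts)):
                bad = np.argwhere(~np.isfinite(self.counts))[0]
                raise ValidationError(
                    f"missing/non-finite count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            if not np.all(self.counts == np.round(self.counts)):
                bad = np.argwhere(self.counts != np.round(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def all_zero_genes(self) -> np.ndarray:
        """Boolean mask of genes with zero counts in every sample."""
        return (self.counts == 0).all(axis=1)

    def drop_all_zero(self) -> "CountTable":
        keep = ~self.all_zero_genes()
        return CountTable(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.sample_ids),
            self.counts[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DesignTwoGroup:
    """Assignment of each sample to one of exactly two conditions.

    Condition order defaults to the order of first appearance in the design
    file; it fixes the sign convention of the between-condition difference
    (condition 1 minus condition 2).  An explicit ``condition_order`` keeps
    the sign anchored to the labels when group membership is exchanged.
    """

    assignment: dict[str, str]
    condition_order: tuple[str, str] | None = None
    conditions: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for lab in self.assignment.values():
            if lab not in seen:
                seen.append(lab)
        if len(seen) != 2:
            raise ValidationError(
                f"exactly two conditions are required, got {len(seen)}: {seen}"
            )
        if self.condition_order is not None:
            if set(self.condition_order) != set(seen):
                raise ValidationError("condition_order does not match the labels present")
            self.conditions = (self.condition_order[0], self.condition_order[1])
        else:
            self.conditions = (seen[0], seen[1])
        for lab in seen:
            n = sum(1 for v in self.assignment.values() if v == lab)
            if n < 2:
                raise ValidationError(
                    f"condition {lab!r} has {n} sample(s); two or more replicates "
                    "per condition are required"
                )

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids of one condition, in canonical (sorted) order."""
        return sorted(s for s, c in self.assignment.items() if c == condition)

    def swapped(self) -> "DesignTwoGroup":
        """Exchange group membership between the two conditions.

        The condition order is preserved, so condition 1 keeps its label but
        acquires the other group's samples: downstream, M and E are exactly
        negated while A, W and zeta are untouched.
        """
        a, b = self.conditions
        return DesignTwoGroup(
            {s: (b if c == a else a) for s, c in self.assignment.items()},
            condition_order=self.conditions,
        )

    def validate_against(self, counts: CountTable) -> None:
        missing = set(counts.sample_ids) - set(self.assignment)
        extra = set(self.assignment) - set(counts.sample_ids)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")
        if extra:
            raise ValidationError(f"design samples absent from counts: {sorted(extra)}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)


def read_counts(path, allow_rounding: bool = False) -> CountTable:
    """Read a genes x samples count TSV.

    First column: gene identifiers.  Header row: sample identifiers.
    Non-integral counts are rejected unless ``allow_rounding`` is set, in
    which case they are rounded half-even.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError("count table needs a gene-id column and >=1 sample")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    try:
        mat = raw.astype(float).to_numpy()
    except ValueError as e:
        raise ValidationError(f"non-numeric cell in count table: {e}") from e
    if np.any(pd.isna(mat)):
        g, s = np.argwhere(pd.isna(mat))[0]
        raise ValidationError(
            f"missing count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    if allow_rounding:
        mat = np.round(mat)
    return CountTable(gene_ids, sample_ids, mat)


def read_design(path, counts: CountTable | None = None) -> DesignTwoGroup:
    """Read a two-column sample/condition TSV into a two-group design."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError("design needs two columns: sample_id, condition")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    seen = [s for s, _ in pairs]
    if len(set(seen)) != len(seen):
        raise ValidationError("duplicate sample in design")
    design = DesignTwoGroup(dict(pairs))
    if counts is not None:
        design.validate_against(counts)
    return design


def design_from_labels(sample_ids: list[str], labels: list[str]) -> DesignTwoGroup:
    """Build a design from an ordered list of condition labels."""
    if len(sample_ids) != len(labels):
        raise ValidationError("one label per sample is required")
    return DesignTwoGroup(dict(zip(sample_ids, labels)))


# result tables are plain DataFrames; these helpers fix the on-disk dialect

def write_results(results: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write a per-gene result table as TSV (12 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        results.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    for col in ("called", "all_zero", "degenerate"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_counts(counts: CountTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(counts.sample_ids) + "\n")
        buf = _io.StringIO()
        counts.to_frame().to_csv(buf, sep="\t", header=False)
        fh.write(buf.getvalue())
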