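"""Genotype encoding, cohort parsing and genotype-superset construction.

A biallelic genotype call is written with the digits ``1`` (wild-type
allele) and ``2`` (variant allele), so the three possible calls are
``"11"``, ``"12"`` and ``"22"``.  Heterozygotes are canonicalized:
``"21"`` is the same genotype as ``"12"`` and is never stored.

A *genotype superset* is the ordered concatenation of one individual's
calls across all M markers, rendered as a space-separated string such as
``"12 22 11 22 11"``.  Locus order is significant: ``"12 12 22 12 11"``
and ``"12 12 22 11 12"`` are different supersets.  The superset string is
the node identity throughout the package.
"""

from __future__ import annotations

import io
import itertools
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CALLS",
    "MISSING_CODES",
    "GenotypeError",
    "Individual",
    "ParseReport",
    "CohortDataset",
    "SupersetFrequencyTable",
    "canonicalize_call",
    "count_possible_supersets",
    "parse_dataset",
    "load_allele_map",
    "build_superset_table",
    "expand_table",
    "read_frequency_table",
    "write_frequency_table",
]

#: Canonical genotype calls in dosage order (0, 1, 2 copies of allele "2").
CALLS: tuple[str, str, str] = ("11", "12", "22")

#: Tokens treated as a missing call; any of these drops the individual.
MISSING_CODES: frozenset[str] = frozenset({"NA", "00", "--", ""})

_CALL_TO_CODE = {"11": 0, "12": 1, "21": 1, "22": 2}


class GenotypeError(ValueError):
    """Raised for malformed genotype data (bad call, duplicate sample...)."""


def canonicalize_call(raw: str) -> str:
    """Return the canonical form of a two-character numeric genotype call.

    Heterozygote order is irrelevant, so ``"21"`` maps to ``"12"``;
    homozygotes pass through unchanged.

    Raises
    ------
    GenotypeError
        If `raw` is not two characters drawn from ``{1, 2}``.
    """
    code = _CALL_TO_CODE.get(raw)
    if code is None:
        raise GenotypeError(f"invalid genotype call {raw!r}: expected two characters from {{1,2}}")
    return CALLS[code]


def count_possible_supersets(m: int) -> int:
    """Number of distinct genotype supersets over `m` biallelic markers (3**m)."""
    if m < 0:
        raise ValueError(f"marker count must be non-negative, got {m}")
    return 3**m


@dataclass(frozen=True)
class Individual:
    """One genotyped subject: id, group label and superset string."""

    sample_id: str
    group: str
    superset: str


@dataclass(frozen=True)
class ParseReport:
    """Summary of a parse: how many rows survived the missing-call filter."""

    n_input: int
    n_kept: int
    n_dropped: int
    dropped_samples: tuple[str, ...]


@dataclass(frozen=True)
class CohortDataset:
    """A genotyped cohort: M markers, k groups, P individuals.

    Genotypes are stored as a dense ``(P, M)`` uint8 matrix of allele-"2"
    dosages (0 = "11", 1 = "12", 2 = "22").  Group labels are stored as
    indices into `groups`, whose order (order of first declaration or of
    the supplied group list) fixes the k-ordering for all reports.
    """

    marker_names: tuple[str, ...]
    groups: tuple[str, ...]
    sample_ids: tuple[str, ...]
    group_codes: np.ndarray  # (P,) intp, index into groups
    codes: np.ndarray  # (P, M) uint8 dosage matrix
    report: ParseReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.codes.ndim != 2 or self.codes.shape != (len(self.sample_ids), len(self.marker_names)):
            raise ValueError("genotype matrix shape does not match sample/marker counts")
        if len(self.group_codes) != len(self.sample_ids):
            raise ValueError("group label count does not match sample count")
        if len(self.sample_ids) == 0:
            raise GenotypeError("dataset has no individuals")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = np.bincount(self.group_codes, minlength=len(self.groups))
        return {g: int(c) for g, c in zip(self.groups, counts)}

    def superset_strings(self) -> list[str]:
        """Canonical superset string for every individual, in row order."""
        return [" ".join(CALLS[c] for c in row) for row in self.codes]

    @property
    def individuals(self) -> Iterator[Individual]:
        labels = [self.groups[g] for g in self.group_codes]
        for sid, grp, sup in zip(self.sample_ids, labels, self.superset_strings()):
            yield Individual(sid, grp, sup)

    def subset_markers(self, indices: Sequence[int]) -> "CohortDataset":
        """Dataset restricted to the marker columns `indices` (order kept)."""
        idx = list(indices)
        if len(idx) == 0:
            raise ValueError("at least one marker must remain")
        return CohortDataset(
            marker_names=tuple(self.marker_names[i] for i in idx),
            groups=self.groups,
            sample_ids=self.sample_ids,
            group_codes=self.group_codes,
            codes=self.codes[:, idx],
        )

    def to_table(self) -> pd.DataFrame:
        """Genotype table (sample_id, group, one call column per marker)."""
        data = {"sample_id": list(self.sample_ids),
                "group": [self.groups[g] for g in self.group_codes]}
        for j, name in enumerate(self.marker_names):
            data[name] = [CALLS[c] for c in self.codes[:, j]]
        return pd.DataFrame(data)


def load_allele_map(source: str | Path | pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Read a per-marker allele map TSV (columns marker, wild, mutant)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    required = {"marker", "wild", "mutant"}
    if not required.issubset(df.columns):
        raise GenotypeError(f"allele map needs columns {sorted(required)}, got {list(df.columns)}")
    return {str(r.marker): (str(r.wild), str(r.mutant)) for r in df.itertuples()}


def _translate_call(raw: str, marker: str, allele_map: Mapping[str, tuple[str, str]] | None) -> int | None:
    """Raw cell -> dosage code, or None if the cell is a missing-data token."""
    token = raw.strip()
    if token in MISSING_CODES:
        return None
    if len(token) != 2:
        raise GenotypeError(f"invalid genotype call {token!r} at marker {marker}")
    if allele_map is not None and marker in allele_map:
        wild, mutant = allele_map[marker]
        trans = {wild: "1", mutant: "2"}
        try:
            token = trans[token[0]] + trans[token[1]]
        except KeyError:
            raise GenotypeError(
                f"call {raw!r} at marker {marker} uses an allele outside "
                f"the declared map {{{wild}->1, {mutant}->2}}"
            ) from None
    code = _CALL_TO_CODE.get(token)
    if code is None:
        raise GenotypeError(f"invalid genotype call {raw!r} at marker {marker}")
    return code


def parse_dataset(
    source: str | Path | pd.DataFrame,
    allele_map: Mapping[str, tuple[str, str]] | str | Path | None = None,
    groups: Sequence[str] | None = None,
) -> CohortDataset:
    """Parse a genotype table into a :class:`CohortDataset`.

    The table must have columns ``sample_id``, ``group`` and one column per
    marker; marker order follows column order.  Calls may be numeric
    (``11``/``12``/``21``/``22``) or allele-letter pairs (e.g. ``"AG"``)
    resolved through `allele_map`.  Individuals with a missing call at any
    marker are dropped and counted in the attached :class:`ParseReport`
    (no imputation).

    Parameters
    ----------
    source
        Path to a TSV file, or an equivalent DataFrame.
    allele_map
        Per-marker ``{marker: (wild, mutant)}`` letter map, or path to the
        sidecar TSV.  Numeric calls bypass it.
    groups
        Optional declared group set; labels outside it are an error and its
        order fixes group ordering.  By default groups are taken in order
        of first appearance.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df = df.astype(str)
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise GenotypeError("genotype table must have 'sample_id' and 'group' columns")
    marker_names = tuple(c for c in df.columns if c not in ("sample_id", "group"))
    if not marker_names:
        raise GenotypeError("genotype table has no marker columns")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeError(f"duplicate sample_id(s): {dupes}")
    if allele_map is not None and not isinstance(allele_map, Mapping):
        allele_map = load_allele_map(allele_map)

    if groups is not None:
        declared = tuple(groups)
        unknown = sorted(set(df["group"]) - set(declared))
        if unknown:
            raise GenotypeError(f"unknown group label(s): {unknown}")
    else:
        declared = tuple(dict.fromkeys(df["group"]))

    kept_ids: list[str] = []
    kept_groups: list[int] = []
    kept_rows: list[list[int]] = []
    dropped: list[str] = []
    group_index = {g: i for i, g in enumerate(declared)}
    for row in df.itertuples(index=False):
        calls: list[int] = []
        complete = True
        for marker, raw in zip(marker_names, row[2:]):
            code = _translate_call(str(raw), marker, allele_map)
            if code is None:
                complete = False
                break
            calls.append(code)
        if complete:
            kept_ids.append(str(row.sample_id))
            kept_groups.append(group_index[str(row.group)])
            kept_rows.append(calls)
        else:
            dropped.append(str(row.sample_id))

    if not kept_ids:
        raise GenotypeError("no individuals survive the missing-call filter")
    report = ParseReport(
        n_input=len(df), n_kept=len(kept_ids), n_dropped=len(dropped),
        dropped_samples=tuple(dropped),
    )
    return CohortDataset(
        marker_names=marker_names,
        groups=declared,
        sample_ids=tuple(kept_ids),
        group_codes=np.asarray(kept_groups, dtype=np.intp),
        codes=np.asarray(kept_rows, dtype=np.uint8),
        report=report,
    )


@dataclass(frozen=True)
class SupersetFrequencyTable:
    """Per-group counts of every observed genotype superset.

    `counts` is indexed by the canonical superset string (lexicographic
    order) with one integer column per group; `totals` gives the group
    sizes (column sums).
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("superset counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every superset row needs at least one positive count")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def n_supersets(self) -> int:
        return len(self.counts)

    @property
    def n_markers(self) -> int:
        return len(self.counts.index[0].split())

    @property
    def total_individuals(self) -> int:
        return int(self.totals.sum())


def build_superset_table(dataset: CohortDataset) -> SupersetFrequencyTable:
    """Tabulate distinct genotype supersets against group membership counts."""
    supersets = dataset.superset_strings()
    k = len(dataset.groups)
    counter: dict[str, np.ndarray] = {}
    for sup, g in zip(supersets, dataset.group_codes):
        row = counter.get(sup)
        if row is None:
            row = counter[sup] = np.zeros(k, dtype=np.int64)
        row[g] += 1
    counts = pd.DataFrame.from_dict(counter, orient="index", columns=list(dataset.groups))
    counts = counts.sort_index()
    counts.index.name = "superset"
    totals = pd.Series(dataset.group_sizes, index=list(dataset.groups), dtype=np.int64)
    return SupersetFrequencyTable(counts=counts, totals=totals)


def expand_table(freq: SupersetFrequencyTable) -> CohortDataset:
    """Reconstruct a cohort from a frequency table by row expansion.

    Sample ids are synthesized (``s0001``...); the inverse of
    :func:`build_superset_table` up to ids and row order.
    """
    marker_names = tuple(f"M{i + 1}" for i in range(freq.n_markers))
    ids: list[str] = []
    gcodes: list[int] = []
    rows: list[list[int]] = []
    counterid = itertools.count(1)
    for sup, row in freq.counts.iterrows():
        calls = [_CALL_TO_CODE[c] for c in str(sup).split()]
        for gi, g in enumerate(freq.groups):
            for _ in range(int(row[g])):
                ids.append(f"s{next(counterid):04d}")
                gcodes.append(gi)
                rows.append(calls)
    return CohortDataset(
        marker_names=marker_names,
        groups=freq.groups,
        sample_ids=tuple(ids),
        group_codes=np.asarray(gcodes, dtype=np.intp),
        codes=np.asarray(rows, dtype=np.uint8),
    )


def read_frequency_table(source: str | Path | io.TextIOBase) -> SupersetFrequencyTable:
    """Read an S2-style frequency table TSV (superset + per-group counts)."""
    df = pd.read_csv(source, sep="\t", dtype={"superset": str})
    if "superset" not in df.columns or df.shape[1] < 2:
        raise GenotypeError("frequency table needs a 'superset' column and >=1 group column")
    df["superset"] = [
        " ".join(canonicalize_call(c) for c in s.strip().strip('"').split())
        for s in df["superset"]
    ]
    counts = df.set_index("superset").astype(np.int64).sort_index()
    counts.index.name = "superset"
    totals = counts.sum(axis=0)
    return SupersetFrequencyTable(counts=counts, totals=totals)


def write_frequency_table(freq: SupersetFrequencyTable, sink: str | Path | io.TextIOBase) -> None:
    """Write a frequency table in the S2-style TSV layout."""
    freq.counts.to_csv(sink, sep="\t")
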