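"""Leave-one-marker-out (knockout) restructuring and marker ranking.

Removing one SNP from every genotype superset collapses supersets that
differed only at that SNP; the way group-specific node counts restructure
under each single-marker omission identifies the markers that carry the
case/control discrimination.  The marker whose omission leaves the fewest
focal-group-specific supersets is the strongest risk candidate (rank 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2_contingency

from .geno_core import CohortDataset, SupersetFrequencyTable, build_superset_table
from .network import build_network, partition_nodes, specific_fraction

__all__ = [
    "KnockoutResult",
    "KnockoutScan",
    "CRITERIA",
    "omit_marker",
    "knockout_scan",
    "rank_markers",
    "knockout_association_test",
    "scan_report",
]

CRITERIA = ("case_specific_nodes", "case_control_ratio")


@dataclass(frozen=True)
class KnockoutResult:
    """Network summary after omitting one marker (or none, for the baseline).

    `class_counts` maps each exact-membership class (tuple of group labels)
    to its node count; `node_specific` and `individual_fractions` are the
    per-group specific node counts and individuals-basis specific fractions.
    """

    omitted_marker: str | None
    omitted_index: int | None
    n_markers: int
    n_nodes: int
    class_counts: dict[tuple[str, ...], int]
    node_specific: dict[str, int]
    individual_fractions: dict[str, float]


@dataclass(frozen=True)
class KnockoutScan:
    """Baseline plus one :class:`KnockoutResult` per omitted marker."""

    markers: tuple[str, ...]
    focal: str
    reference: str
    full: KnockoutResult
    results: tuple[KnockoutResult, ...]


def omit_marker(freq: SupersetFrequencyTable, index: int) -> SupersetFrequencyTable:
    """Delete one marker position from every superset and merge collapsed rows.

    Rows whose reduced superset strings coincide are merged by summing the
    per-group counts, so column sums (group sizes) are preserved exactly.
    """
    m = freq.n_markers
    if m < 2:
        raise ValueError("cannot omit a marker from a single-marker table")
    if not 0 <= index < m:
        raise IndexError(f"marker index {index} out of range for {m} markers")
    reduced = [
        " ".join(c for j, c in enumerate(str(sup).split()) if j != index)
        for sup in freq.counts.index
    ]
    counts = freq.counts.groupby(pd.Index(reduced, name="superset")).sum().sort_index()
    return SupersetFrequencyTable(counts=counts, totals=freq.totals.copy())


def _summarize(freq: SupersetFrequencyTable, omitted: str | None, index: int | None) -> KnockoutResult:
    net = build_network(freq)
    part = partition_nodes(net)
    return KnockoutResult(
        omitted_marker=omitted,
        omitted_index=index,
        n_markers=freq.n_markers,
        n_nodes=net.n_nodes,
        class_counts=part.class_counts,
        node_specific={g: len(part.specific(g)) for g in net.groups},
        individual_fractions={g: specific_fraction(net, g, basis="individuals")
                              for g in net.groups},
    )


def knockout_scan(dataset: CohortDataset, focal: str, reference: str) -> KnockoutScan:
    """Run the full single-marker omission scan.

    For each of the M markers: omit it, rebuild the network from the
    collapsed frequency table, and record membership-class counts and
    individuals-basis specific fractions, alongside the M-marker baseline.
    `focal` is the disease group being ranked for risk, `reference` the
    comparison group (typically controls).
    """
    if focal == reference:
        raise ValueError("focal and reference groups must differ")
    for g in (focal, reference):
        if g not in dataset.groups:
            raise KeyError(f"unknown group {g!r}; dataset groups are {dataset.groups}")
    freq = build_superset_table(dataset)
    full = _summarize(freq, None, None)
    results = tuple(
        _summarize(omit_marker(freq, i), name, i)
        for i, name in enumerate(dataset.marker_names)
    )
    return KnockoutScan(markers=dataset.marker_names, focal=focal,
                        reference=reference, full=full, results=results)


def _criterion_value(result: KnockoutResult, focal: str, reference: str, criterion: str) -> float:
    f = result.node_specific[focal]
    if criterion == "case_specific_nodes":
        return float(f)
    if criterion == "case_control_ratio":
        r = result.node_specific[reference]
        if r == 0:
            # continuity rule: keep the ranking total when the reference
            # group has no specific nodes left
            return (f + 0.5) / (r + 0.5)
        return f / r
    raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def rank_markers(scan: KnockoutScan, criterion: str = "case_specific_nodes") -> list[str]:
    """Order markers by risk evidence under the chosen restructuring criterion.

    Markers are sorted ascending by the criterion value measured after
    their own omission -- rank 1 (first element) is the marker whose
    removal leaves the fewest focal-specific supersets (or the smallest
    focal/reference ratio), i.e. the strongest risk candidate.  Ties keep
    marker input order (stable sort).
    """
    values = [_criterion_value(r, scan.focal, scan.reference, criterion) for r in scan.results]
    order = sorted(range(len(values)), key=lambda i: values[i])
    return [scan.markers[i] for i in order]


def knockout_association_test(
    full_counts: tuple[int, int], omitted_counts: tuple[int, int]
) -> tuple[float, float]:
    """Yates chi-square for restructuring significance of one omission.

    2x2 table: rows = full network vs omitted network, columns =
    focal-specific vs reference-specific node counts; df=1, two-sided p.
    """
    table = [list(full_counts), list(omitted_counts)]
    flat = [c for row in table for c in row]
    if any(c < 0 for c in flat):
        raise ValueError("node counts must be non-negative")
    if min(sum(full_counts), sum(omitted_counts)) == 0 or \
            min(full_counts[0] + omitted_counts[0], full_counts[1] + omitted_counts[1]) == 0:
        raise ValueError("chi-square test undefined: a table margin is zero")
    res = chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def scan_report(scan: KnockoutScan, criteria: tuple[str, ...] = CRITERIA) -> pd.DataFrame:
    """Tabular knockout report: one row per omitted marker.

    Columns: marker, remaining node count, focal/reference specific node
    counts, individuals-basis fractions, restructuring chi2 and p against
    the full network, and the rank under each requested criterion.
    """
    rankings = {c: rank_markers(scan, c) for c in criteria}
    full = (scan.full.node_specific[scan.focal], scan.full.node_specific[scan.reference])
    rows = []
    for r in scan.results:
        omitted = (r.node_specific[scan.focal], r.node_specific[scan.reference])
        try:
            chi2, p = knockout_association_test(full, omitted)
        except ValueError:
            chi2, p = float("nan"), float("nan")
        row = {
            "marker": r.omitted_marker,
            "n_nodes": r.n_nodes,
            f"{scan.focal}_specific_nodes": omitted[0],
            f"{scan.reference}_specific_nodes": omitted[1],
            f"{scan.focal}_specific_fraction": r.individual_fractions[scan.focal],
            f"{scan.reference}_specific_fraction": r.individual_fractions[scan.reference],
            "chi2": chi2,
            "p": p,
        }
        for c in criteria:
            row[f"rank_{c}"] = rankings[c].index(r.omitted_marker) + 1
        rows.append(row)
    return pd.DataFrame(rows)
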