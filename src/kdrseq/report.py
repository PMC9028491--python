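"""Sample filtering and per-population frequency tables.

Individuals enter the frequency tables only when both amplicons were
recovered (the paired-amplicon filter).  All percentages are carrier
frequencies: the share of retained individuals in a column's population
that exhibit the row's mutation or haplotype, rounded half-up to one
decimal.  The ``Total`` column uses the overall retained count as its
denominator and always equals the row-sum of the population counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from kdrseq.calling import CLASS_AMBIGUOUS, AaCall

TOTAL = "Total"


class DuplicateSampleError(ValueError):
    """The same individual id occurs more than once in the status list."""


class ConsistencyError(ValueError):
    """Calls refer to individuals that are not in the retained set."""


@dataclass(frozen=True)
class SampleStatus:
    """Amplification outcome of one individual across the two regions."""

    individual_id: str
    population: str
    dii_present: bool
    diii_present: bool

    @property
    def retained(self) -> bool:
        return self.dii_present and self.diii_present


def percent(count: int, denominator: int) -> float:
    """Carrier percentage rounded half-up to one decimal place."""
    if denominator == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def filter_paired_samples(
    statuses: Sequence[SampleStatus],
) -> tuple[list[SampleStatus], pd.DataFrame]:
    """Keep individuals with both regions present; report the exclusions.

    Returns ``(retained, exclusions)`` where ``exclusions`` lists every
    dropped individual with the missing region(s).
    """
    seen: set[str] = set()
    for s in statuses:
        if s.individual_id in seen:
            raise DuplicateSampleError(f"duplicate individual id {s.individual_id!r}")
        seen.add(s.individual_id)
    retained = [s for s in statuses if s.retained]
    rows = []
    for s in statuses:
        if s.retained:
            continue
        missing = []
        if not s.dii_present:
            missing.append("DII-S6")
        if not s.diii_present:
            missing.append("DIII-S6")
        rows.append(
            {
                "individual_id": s.individual_id,
                "population": s.population,
                "missing_regions": ";".join(missing),
                "reason": "both_fail" if len(missing) == 2 else "one_fail",
            }
        )
    exclusions = pd.DataFrame(
        rows, columns=["individual_id", "population", "missing_regions", "reason"]
    )
    return retained, exclusions


@dataclass
class FrequencyTable:
    """Carrier counts and percentages, populations as columns plus Total.

    ``counts`` and ``percent`` share index (row labels) and columns;
    ``denominators`` holds the per-column retained-n used for every
    percentage in that column.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    denominators: pd.Series

    def formatted(self) -> pd.DataFrame:
        """Render ``count (pct%)`` cells, e.g. ``290 (73.6%)``."""
        out = self.counts.astype(str).copy()
        for col in self.counts.columns:
            out[col] = [
                f"{c} ({p:.1f}%)"
                for c, p in zip(self.counts[col], self.percent[col])
            ]
        return out

    def to_tsv(self, path: str | Path, label: str = "label") -> None:
        df = self.formatted()
        df.index.name = label
        df.to_csv(path, sep="\t")


def _population_order(statuses: Sequence[SampleStatus]) -> list[str]:
    order: list[str] = []
    for s in statuses:
        if s.population not in order:
            order.append(s.population)
    return order


def _build_table(
    carriers: dict[str, dict[str, set[str]]],
    row_order: Sequence[str],
    statuses: Sequence[SampleStatus],
) -> FrequencyTable:
    populations = _population_order(statuses)
    denom = {p: sum(1 for s in statuses if s.population == p) for p in populations}
    denom[TOTAL] = len(statuses)
    columns = populations + [TOTAL]
    counts = pd.DataFrame(0, index=list(row_order), columns=columns, dtype=int)
    for label in row_order:
        per_pop = carriers.get(label, {})
        for p in populations:
            counts.loc[label, p] = len(per_pop.get(p, set()))
        counts.loc[label, TOTAL] = sum(len(v) for v in per_pop.values())
    pct = pd.DataFrame(
        {
            col: [percent(int(c), denom[col]) for c in counts[col]]
            for col in columns
        },
        index=counts.index,
    )
    return FrequencyTable(
        counts=counts, percent=pct, denominators=pd.Series(denom)
    )


def mutation_frequency_table(
    calls: Iterable[AaCall],
    statuses: Sequence[SampleStatus],
) -> FrequencyTable:
    """Per-mutation carrier counts and frequencies.

    ``statuses`` must be the retained set; a call referring to any other
    individual raises :class:`ConsistencyError`.  Ambiguous calls are
    excluded from carrier counts; an individual carrying a mutation in
    several clones or calls still counts once.  Rows are ordered by
    protein position, then mutant residue.
    """
    by_id = {s.individual_id: s for s in statuses}
    carriers: dict[str, dict[str, set[str]]] = {}
    row_keys: dict[str, tuple[int, str]] = {}
    for call in calls:
        if call.classification == CLASS_AMBIGUOUS:
            continue
        status = by_id.get(call.individual_id)
        if status is None:
            raise ConsistencyError(
                f"call for non-retained individual {call.individual_id!r}"
            )
        label = call.label
        row_keys[label] = (call.protein_position, call.alt_residue)
        carriers.setdefault(label, {}).setdefault(status.population, set()).add(
            call.individual_id
        )
    row_order = sorted(row_keys, key=lambda lab: row_keys[lab])
    return _build_table(carriers, row_order, statuses)


INCOMPLETE = "incomplete"


def haplotype_frequency_table(
    haplotypes: dict[str, "object"],
    statuses: Sequence[SampleStatus],
) -> FrequencyTable:
    """Per-haplotype carrier counts and frequencies.

    ``haplotypes`` maps individual id -> :class:`~kdrseq.haplotypes.Haplotype`.
    Incomplete haplotypes appear in a separate ``incomplete`` row whose
    percentage is reported against the same retained-n denominators;
    labelled rows are ordered H-labels first (numerically), then novel
    labels in first-seen order, with ``incomplete`` last.
    """
    by_id = {s.individual_id: s for s in statuses}
    carriers: dict[str, dict[str, set[str]]] = {}
    order: list[str] = []
    for ind_id, hap in haplotypes.items():
        status = by_id.get(ind_id)
        if status is None:
            raise ConsistencyError(f"haplotype for non-retained individual {ind_id!r}")
        label = hap.label if hap.complete else INCOMPLETE
        if label not in order:
            order.append(label)
        carriers.setdefault(label, {}).setdefault(status.population, set()).add(ind_id)

    def sort_key(label: str):
        if label == INCOMPLETE:
            return (2, 0, "")
        if label.startswith("H") and label[1:].isdigit():
            return (0, int(label[1:]), "")
        return (1, order.index(label), label)

    row_order = sorted(order, key=sort_key)
    return _build_table(carriers, row_order, statuses)


def population_shares(statuses: Sequence[SampleStatus]) -> pd.DataFrame:
    """Share of retained individuals contributed by each population.

    Mirrors the cohort-composition summary: per population the retained
    sequence count and its percentage of the overall retained total.
    """
    populations = _population_order(statuses)
    total = len(statuses)
    rows = []
    for p in populations:
        count = sum(1 for s in statuses if s.population == p)
        rows.append({"population": p, "n": count, "share_pct": percent(count, total)})
    return pd.DataFrame(rows, columns=["population", "n", "share_pct"])
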