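"""Expressed-gene census from per-array present/absent calls.

A gene counts as expressed at a timepoint only when it is called present on
every available replicate array of that (accession, day) group — the
all-replicates consensus rule. The census aggregates these calls into
per-timepoint sets, per-accession unions, the overall union, and Venn-style
overlap counts between accessions, and can report the genes never detected
anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .core_data import DetectionFlags, SampleTable, ValidationError

__all__ = ["ExpressionCensus", "call_expressed", "venn_counts", "absent_everywhere"]


@dataclass(frozen=True)
class ExpressionCensus:
    """Sets of expressed genes at several granularities.

    `per_timepoint` maps (accession, day) to the genes passing the
    all-replicates rule there; `per_accession` is the union over that
    accession's timepoints; `overall` the union over accessions. Because the
    emulated design may require presence at "at least one timepoint", both
    the per-timepoint and union granularities are exposed.
    """

    per_timepoint: dict  # (accession, day) -> frozenset of gene ids
    per_accession: dict  # accession -> frozenset
    overall: frozenset

    def timepoint_counts(self) -> pd.DataFrame:
        rows = [
            {"accession": acc, "day": day, "n_expressed": len(genes)}
            for (acc, day), genes in sorted(self.per_timepoint.items())
        ]
        return pd.DataFrame(rows)

    def accession_counts(self) -> dict:
        return {acc: len(genes) for acc, genes in self.per_accession.items()}

    def intersection_counts(self) -> dict:
        """Pairwise (and, if >2 accessions, triple) intersection sizes."""
        out = {}
        accs = sorted(self.per_accession)
        for r in (2, 3):
            for combo in combinations(accs, r):
                inter = frozenset.intersection(*(self.per_accession[a] for a in combo))
                out["&".join(combo)] = len(inter)
        return out


def call_expressed(flags: DetectionFlags, samples: SampleTable) -> ExpressionCensus:
    """Apply the all-replicates consensus rule per (accession, day) group.

    With a lost replicate the rule generalizes to "present on all available
    replicates" for that group. A group with zero replicate arrays is an error.
    """
    sample_ids = set(flags.sample_ids)
    missing = [s for s in samples.sample_ids if s not in sample_ids]
    if missing:
        raise ValidationError(f"flags missing sample columns: {missing[:5]}")

    genes = pd.Index(flags.gene_ids)
    per_timepoint: dict = {}
    per_accession: dict = {}
    for (acc, day), grp in samples.data.groupby(["accession", "day"], sort=False):
        cols = list(grp["sample_id"])
        if not cols:
            raise ValidationError(f"no replicates for ({acc}, day {day})")
        expressed = frozenset(genes[flags.data[cols].all(axis=1).to_numpy()])
        per_timepoint[(acc, int(day))] = expressed
        per_accession.setdefault(acc, frozenset())
        per_accession[acc] = per_accession[acc] | expressed
    overall = frozenset().union(*per_accession.values()) if per_accession else frozenset()
    return ExpressionCensus(per_timepoint, per_accession, overall)


def venn_counts(named_sets: dict) -> pd.DataFrame:
    """Counts of every region of the 2- or 3-set Venn partition.

    `named_sets` maps set name to an iterable of gene ids. Each region is
    keyed by the membership pattern (e.g. 'A&B-C' means in A and B, not C);
    region counts sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValidationError("venn_counts needs at least 2 named sets")
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())
    rows = []
    # every non-empty membership pattern
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            label = "&".join(inside) + ("".join(f"-{n}" for n in outside))
            rows.append({"region": label, "count": len(region)})
    df = pd.DataFrame(rows)
    assert df["count"].sum() == len(universe)
    return df


def absent_everywhere(census: ExpressionCensus, universe) -> frozenset:
    """Genes in `universe` never expressed at any timepoint of any accession."""
    return frozenset(universe) - census.overall
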