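"""Mutant-validation decision rules and expression-phenotype concordance.

A candidate gene from the association scan is validated by studying
independent insertion (knockout) mutants: a gene with at least two mutants
showing significantly altered rosette growth versus wild-type Col-0 is
called a chilling-tolerance gene ("validated"); one significant mutant
among several tested leaves it a "strong candidate".  Concordance then
relates the direction of the gene's cold-stress expression change to the
growth response of its knockouts: a gene repressed in the cold whose
knockouts grow *better* than Col-0 behaves as a negative regulator of
chilling tolerance, and a cold-induced gene whose knockouts grow worse as
a positive regulator.

The two curated gene tables of the validation study (16 chilling-tolerance
genes, 9 strong candidates) ship with the package as TSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MutantEntry",
    "GeneValidationRecord",
    "classify_validation",
    "concordance_class",
    "summarize_concordance",
    "overlap_percentage",
    "load_table1",
    "load_table2",
    "records_from_frame",
]

VALIDATED = "validated"
STRONG_CANDIDATE = "strong_candidate"
REJECTED = "rejected"
INSUFFICIENT = "insufficient"

CONCORDANT_NEGATIVE = "concordant_negative_regulator"
CONCORDANT_POSITIVE = "concordant_positive_regulator"
DISCORDANT = "discordant"
INDETERMINATE = "indeterminate"


@dataclass
class MutantEntry:
    """One insertion mutant: its growth ratio vs Col-0 and significance call."""

    mutant_id: str
    growth_ratio: float
    significant: bool


@dataclass
class GeneValidationRecord:
    """One gene's expression ratio, mutant outcomes and scan provenance."""

    gene_id: str
    protein: str = ""
    expression_ratio: float | None = None  # cold / normal transcript ratio
    mutants: list = field(default_factory=list)
    algorithms: tuple = ()  # subset of {"EMMAX", "LR"}
    previously_reported: bool = False

    def __post_init__(self):
        if not self.mutants:
            raise ValueError(f"{self.gene_id}: need at least one mutant entry")
        if self.expression_ratio is not None and not self.expression_ratio > 0:
            raise ValueError(f"{self.gene_id}: expression ratio must be positive")

    @property
    def mutant_ratios(self) -> np.ndarray:
        return np.array([m.growth_ratio for m in self.mutants], dtype=float)


def classify_validation(record: GeneValidationRecord) -> str:
    """Validation outcome from the per-mutant significance calls.

    >= 2 significant mutants -> validated; exactly one significant among
    >= 2 tested -> strong_candidate; none significant among >= 2 tested ->
    rejected; a single tested mutant is insufficient evidence either way.
    """
    n_tested = len(record.mutants)
    n_sig = sum(1 for m in record.mutants if m.significant)
    if n_sig >= 2:
        return VALIDATED
    if n_tested < 2:
        return INSUFFICIENT
    return STRONG_CANDIDATE if n_sig == 1 else REJECTED


def concordance_class(expression_ratio: float, mutant_ratios) -> str:
    """Relate a gene's cold-expression change to its knockouts' growth.

    Uses the mean of the gene's mutant growth ratios (a single outlier
    mutant, e.g. a promoter insertion, does not flip the gene's call).
    Repressed gene (ratio < 1) with enhanced knockout growth (mean > 1) is
    a concordant negative regulator; induced gene (> 1) with reduced
    knockout growth (mean < 1) a concordant positive regulator.  Exact ties
    at 1 are indeterminate, never silently concordant.
    """
    ratios = np.asarray(mutant_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty mutant ratio list")
    if expression_ratio is None:
        raise ValueError("expression ratio missing")
    m = ratios.mean()
    if expression_ratio == 1 or m == 1:
        return INDETERMINATE
    if expression_ratio < 1 and m > 1:
        return CONCORDANT_NEGATIVE
    if expression_ratio > 1 and m < 1:
        return CONCORDANT_POSITIVE
    return DISCORDANT


def summarize_concordance(records) -> dict:
    """Tally concordance classes over a set of gene records.

    Genes without an expression ratio are counted as unclassified.
    """
    counts = {
        "concordant_negative": 0,
        "concordant_positive": 0,
        "discordant": 0,
        "indeterminate": 0,
        "unclassified": 0,
        "n_genes": 0,
    }
    for rec in records:
        counts["n_genes"] += 1
        if rec.expression_ratio is None:
            counts["unclassified"] += 1
            continue
        cls = concordance_class(rec.expression_ratio, rec.mutant_ratios)
        if cls == CONCORDANT_NEGATIVE:
            counts["concordant_negative"] += 1
        elif cls == CONCORDANT_POSITIVE:
            counts["concordant_positive"] += 1
        elif cls == DISCORDANT:
            counts["discordant"] += 1
        else:
            counts["indeterminate"] += 1
    counts["total_concordant"] = (
        counts["concordant_negative"] + counts["concordant_positive"]
    )
    return counts


def overlap_percentage(records) -> float:
    """Percent of genes already reported in earlier genetic studies."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    n_prev = sum(1 for r in records if r.previously_reported)
    return 100.0 * n_prev / len(records)


def records_from_frame(df: pd.DataFrame) -> list:
    """Build GeneValidationRecords from a long-format gene/mutant table.

    Expected columns: gene_id, protein, expression_ratio (may be NA),
    mutant_id, growth_ratio, significant, algorithms (comma-separated),
    previously_reported.
    """
    records = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        first = sub.iloc[0]
        expr = first.get("expression_ratio")
        expr = None if pd.isna(expr) else float(expr)
        records.append(
            GeneValidationRecord(
                gene_id=str(gene_id),
                protein=str(first.get("protein", "")),
                expression_ratio=expr,
                mutants=[
                    MutantEntry(
                        mutant_id=str(r.mutant_id),
                        growth_ratio=float(r.growth_ratio),
                        significant=bool(int(r.significant)),
                    )
                    for r in sub.itertuples()
                ],
                algorithms=tuple(str(first.get("algorithms", "")).split(",")),
                previously_reported=bool(int(first.get("previously_reported", 0))),
            )
        )
    return records


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("phenotray.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1(as_records: bool = True):
    """The 16 validated chilling-tolerance genes with their 34 mutants."""
    df = _load_fixture("table1_chilling_tolerance_genes.tsv")
    return records_from_frame(df) if as_records else df


def load_table2(as_records: bool = True):
    """The 9 strong-candidate genes (one altered mutant each)."""
    df = _load_fixture("table2_strong_candidate_genes.tsv")
    return records_from_frame(df) if as_records else df
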