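"""Taxa x samples abundance tables: species aggregation, crosstalk /
prevalence filters, rarefaction, and phyloseq-ready CSV export.

The table is the OTU-table analogue of the pipeline output: taxa as rows,
samples as columns.  Every filter is appended to an ordered ``filter_log``
so that the final table is exactly reproducible from the raw one by
replaying the log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify_em import RANKS, AbundanceEstimate, ReferenceDB


@dataclass
class AbundanceTable:
    """Counts (taxa x samples) + per-taxon taxonomy + sample metadata.

    ``counts`` may hold EM-estimated (fractional) counts until
    :func:`rarefy`, which requires integers and rounds first.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("taxon and sample labels must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def _logged(self, counts=None, taxonomy=None, **entry) -> "AbundanceTable":
        return AbundanceTable(
            counts=self.counts if counts is None else counts,
            taxonomy=self.taxonomy if taxonomy is None else taxonomy,
            samples=self.samples,
            filter_log=self.filter_log + [entry],
        )


def from_estimates(estimates: dict[str, AbundanceEstimate],
                   db: ReferenceDB,
                   sample_metadata: pd.DataFrame | None = None) -> AbundanceTable:
    """Assemble the raw taxid x sample table from per-sample EM output."""
    counts = pd.DataFrame(
        {s: pd.Series(est.est_counts) for s, est in estimates.items()}
    ).fillna(0.0)
    counts.index.name = "taxid"
    tax = db.taxonomy_frame().loc[counts.index]
    samples = (sample_metadata if sample_metadata is not None
               else pd.DataFrame(index=list(estimates)))
    return AbundanceTable(counts, tax, samples)


def aggregate_species(table: AbundanceTable) -> AbundanceTable:
    """Collapse taxa on (genus, species).

    Rows with a blank genus are removed entirely; a blank species becomes
    "Unclassified" within its genus.  Row labels become "Genus species".
    """
    tax = table.taxonomy.copy()
    keep = tax["genus"].fillna("").str.strip() != ""
    tax = tax[keep]
    counts = table.counts.loc[tax.index]
    species = tax["species"].fillna("").str.strip().replace("", "Unclassified")
    # label is "genus species", except binomial species strings already
    # starting with the genus are used as-is
    labels = [sp if sp.startswith(g + " ") or sp == g else f"{g} {sp}"
              for g, sp in zip(tax["genus"], species)]
    grouped = counts.groupby(pd.Index(labels, name="taxon")).sum()
    tax_out = tax.assign(species=species.values, taxon=labels)
    tax_out = tax_out.groupby("taxon").first().loc[grouped.index]
    return AbundanceTable(
        grouped, tax_out, table.samples,
        table.filter_log + [{"op": "aggregate_species"}],
    )


def apply_crosstalk_filter(table: AbundanceTable,
                           threshold: float) -> AbundanceTable:
    """Zero any per-sample relative abundance strictly below ``threshold``.

    ``threshold`` is a proportion (the crosstalk rate measured from null
    barcode controls, e.g. 7.3e-5 for 0.0073%).  Cells are zeroed
    per-sample; rows left all-zero are then dropped.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts / totals.replace(0, np.nan)
    counts[rel.fillna(0.0) < threshold] = 0
    # rows zeroed out by this filter are dropped; rows that entered all-zero
    # are left alone (the filter is per-sample, not a row deletion rule)
    was_nonzero = table.counts.sum(axis=1) > 0
    keep = (counts.sum(axis=1) > 0) | ~was_nonzero
    return table._logged(
        counts=counts[keep], taxonomy=table.taxonomy.loc[keep[keep].index],
        op="apply_crosstalk_filter", threshold=threshold,
    )


def prevalence_filter(table: AbundanceTable, min_reads: int = 5,
                      min_samples: int = 3) -> AbundanceTable:
    """Keep taxa present at more than ``min_reads`` reads (strict) in at
    least ``min_samples`` samples."""
    keep = (table.counts > min_reads).sum(axis=1) >= min_samples
    return table._logged(
        counts=table.counts[keep], taxonomy=table.taxonomy.loc[keep[keep].index],
        op="prevalence_filter", min_reads=min_reads, min_samples=min_samples,
    )


def rarefy(table: AbundanceTable, depth: int = 1900,
           seed: int = 42) -> AbundanceTable:
    """Subsample every sample without replacement to a common depth.

    Counts are rounded to integers first (EM counts are fractional).
    Samples below ``depth`` are dropped with a warning; each surviving
    column is one seeded multivariate-hypergeometric draw, so identical
    seeds give identical tables.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    ints = table.counts.round().astype(np.int64)
    kept_cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample in ints.columns:
        col = ints[sample].to_numpy()
        if col.sum() < depth:
            dropped.append(sample)
            continue
        kept_cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        warnings.warn(f"rarefy: dropped samples below depth {depth}: {dropped}")
    counts = pd.DataFrame(kept_cols, index=ints.index)
    return AbundanceTable(
        counts, table.taxonomy, table.samples,
        table.filter_log + [{"op": "rarefy", "depth": depth, "seed": seed,
                             "dropped_samples": dropped}],
    )


def replay_filters(raw: AbundanceTable, filter_log: list[dict]) -> AbundanceTable:
    """Re-run a logged filter sequence on a raw table."""
    ops = {
        "aggregate_species": lambda t, e: aggregate_species(t),
        "apply_crosstalk_filter":
            lambda t, e: apply_crosstalk_filter(t, e["threshold"]),
        "prevalence_filter":
            lambda t, e: prevalence_filter(t, e["min_reads"], e["min_samples"]),
        "rarefy": lambda t, e: rarefy(t, e["depth"], e["seed"]),
    }
    table = raw
    for entry in filter_log:
        table = ops[entry["op"]](table, entry)
    return table


def export_phyloseq_csv(table: AbundanceTable, out_dir) -> dict[str, Path]:
    """Write otu_table.csv, tax_table.csv, sample_data.csv, filter_log.tsv.

    The sample sheet uses a Qiime-style mapping with ``#SampleID`` as the
    first column.  Files round-trip losslessly (see
    :func:`read_phyloseq_csv` and the R bridge script).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu": out / "otu_table.csv",
        "tax": out / "tax_table.csv",
        "samples": out / "sample_data.csv",
        "log": out / "filter_log.tsv",
    }
    otu = table.counts.copy()
    otu.index.name = otu.index.name or "taxon"
    otu.to_csv(paths["otu"])
    tax = table.taxonomy[list(RANKS)].copy()
    tax.index = otu.index
    tax.to_csv(paths["tax"])
    samples = table.samples.copy()
    if samples.empty and len(table.counts.columns):
        samples = pd.DataFrame(index=table.counts.columns)
    samples.index.name = "#SampleID"
    samples.to_csv(paths["samples"])
    pd.DataFrame(table.filter_log).to_csv(paths["log"], sep="\t", index=False)
    return paths


def read_phyloseq_csv(out_dir) -> AbundanceTable:
    out = Path(out_dir)
    otu = pd.read_csv(out / "otu_table.csv", index_col=0)
    tax = pd.read_csv(out / "tax_table.csv", index_col=0,
                      dtype=str, keep_default_na=False)
    samples = pd.read_csv(out / "sample_data.csv", index_col=0)
    return AbundanceTable(otu, tax, samples)
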