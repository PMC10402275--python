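"""End-to-end orchestration of the synthetic benchmark pipeline.

Wires the stages together in protocol order — simulate, concatemer
injection, adapter splitting, Q10 filtering, dual-barcode demultiplexing,
primer trimming, per-sample EM classification, table filtering — and
collects per-stage run statistics plus recovery metrics against the truth
manifest.  This is what the worked example, the end-to-end tests and the
acceptance script all run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc_filter, splitcat, synthetic, tables_export
from .classify_em import AbundanceEstimate, ReferenceDB, classify_sample
from .demux import BarcodeScheme, DemuxResult, demultiplex, estimate_crosstalk_threshold
from .seqio import Read, RunStats, summarize_run
from .tables_export import AbundanceTable
from .trim_extract import PrimerPair, rrn_primers, trim_reads


@dataclass
class PipelineResult:
    db: ReferenceDB
    scheme: BarcodeScheme
    composition: dict[str, dict[int, float]]
    manifest: pd.DataFrame
    split_report: splitcat.SplitReport
    demux_result: DemuxResult
    crosstalk_threshold: float
    estimates: dict[str, AbundanceEstimate]
    n_unclassified: dict[str, int]
    raw_table: AbundanceTable
    table: AbundanceTable
    stage_stats: list[RunStats] = field(default_factory=list)

    def estimated_proportions(self) -> pd.DataFrame:
        """EM relative abundances (taxid x sample), for truth comparison."""
        return pd.DataFrame({s: pd.Series(e.abundances)
                             for s, e in self.estimates.items()}).fillna(0.0)

    def max_abundance_error(self) -> float:
        """Largest per-taxon |estimated - configured| proportion, with both
        sides averaged over replicate samples.

        Mock replicates are averaged before comparison (the convention for
        reporting mock-community recovery); per-sample deviations also
        carry the multinomial sampling noise of the finite read draw,
        which is a property of the sample, not of the estimator.
        """
        est = self.estimated_proportions()
        samples = [s for s in self.composition if s in est.columns]
        worst = 0.0
        for taxid in est.index:
            got = float(est.loc[taxid, samples].mean())
            truth = float(np.mean([self.composition[s].get(taxid, 0.0)
                                   for s in samples]))
            worst = max(worst, abs(got - truth))
        return worst


def mock_composition(db: ReferenceDB, n_mock_taxa: int = 8) -> dict[int, float]:
    """Known-composition mixture over the first taxa of the database,
    using the theoretical proportions of the 8-species commercial mock."""
    props = list(synthetic.MOCK_COMPOSITION.values())[:n_mock_taxa]
    taxids = [e.taxid for e in db.entries[:n_mock_taxa]]
    total = sum(props)
    return {t: p / total for t, p in zip(taxids, props)}


def run_synthetic_pipeline(
    config: synthetic.SimConfig,
    composition: dict[str, dict[int, float]] | None = None,
    primers: PrimerPair | None = None,
    max_mismatch: int = 0,
    rarefy_depth: int = 1000,
    min_reads: int = 5,
    min_samples: int = 3,
) -> PipelineResult:
    """Run the whole pipeline on one simulated multiplexed run.

    With ``composition=None`` every sample is the 8-taxon mock mixture
    over a database of ``config.n_taxa`` taxa.  The crosstalk threshold is
    estimated from the run's own null barcode controls and applied to the
    final table after aggregation, rarefaction and prevalence filtering.
    """
    primers = primers or rrn_primers()
    db = synthetic.build_reference(config)
    scheme = synthetic.make_scheme(config.n_samples, seed=config.seed)
    if composition is None:
        mock = mock_composition(db)
        composition = {s: dict(mock) for s in sorted(scheme.sample_map.values())}

    reads, manifest = synthetic.simulate_reads(db, scheme, composition, config)
    reads, manifest = synthetic.inject_concatemers(
        reads, manifest, config.concatemer_fraction, config.seed,
        adapter=config.adapter)
    stats = [summarize_run(reads, "0-simulated")]

    reads, split_report = splitcat.split_concatemers(reads, config.adapter)
    stats.append(summarize_run(reads, "1-read_splitting"))

    reads = qc_filter.filter_by_quality(reads, 10.0)
    stats.append(summarize_run(reads, "2-q10_filter"))

    demux_result = demultiplex(reads, scheme, max_mismatch=max_mismatch)
    threshold = estimate_crosstalk_threshold(demux_result)

    estimates: dict[str, AbundanceEstimate] = {}
    n_unclassified: dict[str, int] = {}
    trimmed_all: list[Read] = []
    for sample, sample_reads in sorted(demux_result.assigned.items()):
        if not sample_reads:
            continue
        trimmed, _ = trim_reads(sample_reads, primers)
        trimmed_all.extend(trimmed)
        if trimmed:
            estimates[sample], n_unclassified[sample] = classify_sample(
                trimmed, db)
    stats.append(summarize_run(trimmed_all, "3-trimmed"))

    raw = tables_export.from_estimates(estimates, db)
    table = tables_export.aggregate_species(raw)
    table = tables_export.rarefy(table, depth=rarefy_depth, seed=config.seed)
    table = tables_export.prevalence_filter(table, min_reads, min_samples)
    table = tables_export.apply_crosstalk_filter(table, threshold)

    return PipelineResult(
        db=db, scheme=scheme, composition=composition, manifest=manifest,
        split_report=split_report, demux_result=demux_result,
        crosstalk_threshold=threshold, estimates=estimates,
        n_unclassified=n_unclassified, raw_table=raw, table=table,
        stage_stats=stats,
    )
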