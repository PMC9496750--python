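"""End-to-end orchestration: simulate/load -> detect -> impute -> stats ->
FDR -> calls -> clients -> features -> summaries, with a provenance
manifest.

Every run writes TSV result tables plus ``manifest.json`` recording the
effective configuration and its hash, the seed, per-stage row counts,
input-file digests and the package version.  Given the same configuration
and seed, result tables are byte-identical across reruns (the manifest
timestamp is the only run-specific field, and it lives outside the
tables)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from . import clients as cl
from . import diff as da
from . import proteome_io as pio
from . import signals as sig
from . import synthetic as syn

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Either ``lfq_path``/``design_path``/``annotations_path`` point at real
    input files, or (when ``lfq_path`` is None) a synthetic cohort is
    generated with the ``synthetic`` parameters.
    """

    seed: int = 0
    # input files (optional; synthetic cohort generated when absent)
    lfq_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    cds_path: str | None = None
    codon_rates_path: str | None = None
    pathway: str = "knockdown"
    # synthetic-cohort parameters
    n_proteins: int = 2000
    n_replicates: int = 3
    n_experiments: int = 1
    synthetic: syn.TruthConfig = field(default_factory=syn.TruthConfig)
    # statistical thresholds
    alpha: float = 0.05
    n_perm: int | None = None  # None = exhaustive when feasible
    t_test_method: str = "student"
    s0: float | str = "auto"
    pi0: float | None = None
    impute_shift: float = 1.8
    impute_width: float = 0.3
    tail_window: int = 30
    triage_p: float = 0.01
    triage_min_reduction: float = 0.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


@dataclass
class PipelineResult:
    """In-memory handles to the main run outputs."""

    out_dir: Path
    cohort: pio.LfqCohort
    calls: pd.DataFrame
    client_records: list[cl.ClientRecord]
    truth: syn.SyntheticTruth | None = None


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    resume: bool = False,
) -> PipelineResult:
    """Execute every stage and write result tables + manifest to ``out_dir``.

    With ``resume=True``, stages whose output tables already exist under
    ``out_dir`` are not recomputed (cached-stage resume for partial reruns).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    inputs: dict[str, str] = {}
    truth = None
    annotations: Mapping[str, pio.ProteinAnnotation]

    # --- load or simulate -------------------------------------------------
    if config.lfq_path is not None:
        for name, p in (("lfq", config.lfq_path), ("design", config.design_path),
                        ("annotations", config.annotations_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input file for {name!r} not found: {p}")
            inputs[name] = _digest(p)
        cohort = pio.read_lfq_table(config.lfq_path, config.design_path)
        annotations = pio.read_annotations(config.annotations_path)
        cds = pio.read_fasta(config.cds_path) if config.cds_path else {}
        rates = (pio.read_codon_rates(config.codon_rates_path)
                 if config.codon_rates_path else None)
    else:
        cohort, annotations, truth = syn.generate_cohort(
            config.n_proteins, config.n_replicates, config.n_experiments,
            config.synthetic, config.seed,
        )
        cds = syn.generate_cds(annotations, seed=config.seed + 1)
        rates = syn.generate_codon_rate_table(seed=config.seed + 2)
    counts["quantified"] = cohort.n_proteins

    # --- detection filter + imputation ------------------------------------
    detected = da.filter_detected(cohort)
    cohort_detected = cohort.subset(sorted(detected))
    counts["detected_in_all"] = cohort_detected.n_proteins
    imputed = da.impute_missing(
        cohort_detected, width=config.impute_width, shift=config.impute_shift,
        seed=config.seed + 3,
    )

    # --- per-siRNA stats + permutation FDR + calls -------------------------
    calls_path = out / "calls.tsv"
    sirna_groups = [g for g in imputed.groups if g != "control"]
    diffs: dict[str, pd.DataFrame] = {}
    for k, group in enumerate(sirna_groups):
        diff_path = out / f"diff_{group}.tsv"
        if resume and diff_path.exists():
            diffs[group] = pd.read_csv(diff_path, sep="\t", index_col="accession")
            continue
        diffs[group] = da.diff_table(
            imputed, group, n_perm=config.n_perm, seed=config.seed + 10 + k,
            method=config.t_test_method, s0=config.s0, pi0=config.pi0,
        )
        _write_table(diffs[group], diff_path)
    if resume and calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t", index_col="accession")
    else:
        calls = da.call_affected(diffs["sirna1"], diffs["sirna2"], alpha=config.alpha)
        _write_table(calls, calls_path)
    negative, positive = da.affected_sets(calls)
    counts["affected_negative"] = len(negative)
    counts["affected_positive"] = len(positive)
    _write_table(da.volcano_table(diffs), out / "volcano.tsv", index=False)

    # --- client catalogue ---------------------------------------------------
    records = cl.build_client_records(sorted(negative), annotations, config.pathway,
                                      tail_window=config.tail_window)
    counts["clients"] = len(records)
    _write_table(cl.client_table(records), out / "clients.tsv", index=False)

    # --- enrichment + composition summaries ---------------------------------
    background = set(imputed.proteins)
    summary: dict = {"pathway": config.pathway}
    if negative:
        for label, pred in (
            ("sp", lambda a: a.has_sp),
            ("nglyc", lambda a: bool(a.n_glyc_sites)),
            ("membrane", lambda a: a.n_tmh > 0),
        ):
            enr = cl.enrichment_factor(pred, negative, background, annotations)
            summary[f"{label}_fold"] = enr.fold
            summary[f"{label}_fraction_affected"] = enr.fraction_affected
            summary[f"{label}_fraction_background"] = enr.fraction_background
            summary[f"{label}_p_hypergeom"] = enr.p_value
        summary["compartments_affected"] = cl.compartment_composition(negative, annotations)
    summary["compartments_background"] = cl.compartment_composition(background, annotations)

    # --- targeting-signal features ------------------------------------------
    client_acc = [r.accession for r in records]
    features = sig.signal_feature_table(annotations, accessions=client_acc)
    _write_table(features, out / "signal_features.tsv", index=False)
    if cds and rates is not None and client_acc:
        times_clients = sig.translation_time_table(cds, rates, accessions=client_acc)
        times_all = sig.translation_time_table(cds, rates,
                                               accessions=sorted(background & set(cds)))
        _write_table(times_clients, out / "translation_times_clients.tsv", index=False)
        if len(times_clients) and len(times_all):
            u, p = sig.rank_sum_compare(times_clients["total_time_s"],
                                        times_all["total_time_s"])
            summary["translation_time_rank_sum_u"] = u
            summary["translation_time_rank_sum_p"] = p

    # --- per-pathway client summary ------------------------------------------
    report = summary_report({config.pathway: records})
    _write_table(report, out / "client_summary.tsv", index=False)
    with open(out / "enrichment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)

    manifest = {
        "package": "erclients",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": inputs,
        "stage_counts": counts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "tables": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline funnel: %s", counts)
    return PipelineResult(out_dir=out, cohort=imputed, calls=calls,
                          client_records=records, truth=truth)


def summary_report(
    clients_by_pathway: Mapping[str, Sequence[cl.ClientRecord]],
) -> pd.DataFrame:
    """Per-pathway client summary: SP/TMH percentages, class composition,
    TMH-position mean +/- sd and bin distribution."""
    rows = []
    for pathway, records in clients_by_pathway.items():
        n = len(records)
        row: dict = {"pathway": pathway, "n_clients": n}
        if n == 0:
            rows.append(row)
            continue
        row["pct_sp"] = 100.0 * sum(r.has_sp for r in records) / n
        row["pct_tmh"] = 100.0 * sum(r.first_tmh_rel_pos is not None for r in records) / n
        row["pct_nglyc"] = 100.0 * sum(r.n_glycosylated for r in records) / n
        for cls in cl.CLIENT_CLASSES:
            row[f"pct_{cls}"] = 100.0 * sum(r.client_class == cls for r in records) / n
        try:
            pos = cl.position_summary(records)
        except ValueError:
            pass
        else:
            row["tmh_pos_mean"] = pos.mean
            row["tmh_pos_sd"] = pos.sd
            for b, frac in pos.bin_fractions.items():
                row[f"bin_{b}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def venn_counts(sets_by_label: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap counts between client sets (Venn report)."""
    labels = list(sets_by_label)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            rows.append({
                "set_a": a, "set_b": b,
                "n_a": len(sets_by_label[a]), "n_b": len(sets_by_label[b]),
                "overlap": len(sets_by_label[a] & sets_by_label[b]),
            })
    return pd.DataFrame(rows)


__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "summary_report", "venn_counts"]
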