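"""Synthetic knockdown cohorts with known ground truth.

The generator emulates the design of the real experiments: one control
(non-targeting siRNA) group and two targeting-siRNA groups, three
replicates each, optionally several independent experiments.  Protein-level
log2 intensities are

    log2 I = baseline_i + experiment intercept + group effect + N(0, noise_sd)

with the group effect equal to the planted per-protein knockdown effect in
the targeting groups and 0 in the control.  Missingness is
missing-not-at-random (probability rising logistically as the log2
intensity falls below a low-intensity threshold) plus a small completely-
at-random component.

Annotations are drawn so that the fractions of signal-peptide-bearing,
N-glycosylated and membrane proteins match configured targets (defaults
7% / 10% / 14%, the composition of a deeply quantified HeLa proteome).
Membrane clients are spread over the type I / tail-anchored / single-span /
multi-spanning / hairpin classes, TMH intervals are placed consistently
with the sampled class, and amino-acid sequences are generated with
hydrophobic cores inside TMH windows and SP H-regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import proteome_io as pio
from .proteome_io import CodonRateTable, LfqCohort, ProteinAnnotation, SampleDesign
from .scales import CODONS_BY_RESIDUE

logger = logging.getLogger(__name__)

HYDROPHOBIC = "LIVFAM"
POLAR = "STNQGY"
CHARGED_POS = "KR"
MIXED = "ACDEFGHIKLMNPQRSTVWY"

ENDO_EXO_COMPARTMENTS = (
    "ER", "Golgi", "endosome", "lysosome", "plasma_membrane", "secreted",
)
OTHER_COMPARTMENTS = ("cytosol", "nucleus", "mitochondrion")

MEMBRANE_CLASS_SHARES = {
    "type_I": 0.25,
    "single_span_no_sp": 0.20,
    "tail_anchored": 0.15,
    "multi_spanning": 0.35,
    "hairpin": 0.05,
}


@dataclass(frozen=True)
class TruthConfig:
    """Planted-effect and composition parameters of a synthetic cohort.

    Defaults are the study conditions the analysis is designed for: 5%
    clients with a -1 log2 knockdown effect, log-normal baselines spanning
    a typical LFQ dynamic range (log2 mean 25, sd 2), replicate noise of
    0.25 on the log2 scale, and MNAR missingness switched on.
    """

    client_fraction: float = 0.05
    effect_log2: float = -1.0
    upregulated_fraction: float = 0.02
    upregulated_effect_log2: float = 1.0
    conflict_fraction: float = 0.0
    sirna2_attenuation: float = 1.0
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    noise_sd_log2: float = 0.25
    experiment_sd_log2: float = 0.1
    # detection limit ~3 sd below the baseline mean: missingness concentrated
    # at the bottom of the dynamic range, the regime the standard down-shift
    # imputation assumes
    mnar_slope: float = 1.0
    mnar_threshold_log2: float = 19.0
    mcar_rate: float = 0.005
    sp_fraction: float = 0.07
    nglyc_fraction: float = 0.10
    membrane_fraction: float = 0.14
    exact_counts: bool = False

    def __post_init__(self) -> None:
        for name in ("client_fraction", "upregulated_fraction", "conflict_fraction",
                     "sp_fraction", "nglyc_fraction", "membrane_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.client_fraction + self.upregulated_fraction + self.conflict_fraction > 1:
            raise ValueError("client + upregulated + conflict fractions exceed 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")
        type_i_frac = self.membrane_fraction * MEMBRANE_CLASS_SHARES["type_I"]
        if self.sp_fraction < type_i_frac - 1e-12:
            raise ValueError(
                "infeasible composition: sp_fraction smaller than the type I "
                "membrane fraction it must cover"
            )


@dataclass
class SyntheticTruth:
    """Exhaustive ground-truth ledger for one generated cohort."""

    client_accessions: set[str]
    upregulated_accessions: set[str]
    conflict_accessions: set[str]
    effect_log2: dict[str, float]          # per-protein siRNA-1 effect
    effect_log2_sirna2: dict[str, float]   # per-protein siRNA-2 effect
    baseline_log2_mean: float
    baseline_log2_sd: float
    noise_sd_log2: float
    missingness: tuple[float, float]       # (mnar_slope, mcar_rate)
    seed: int
    config: TruthConfig = field(default_factory=TruthConfig)

    def __post_init__(self) -> None:
        if self.client_accessions & self.upregulated_accessions:
            raise ValueError("client and upregulated sets must be disjoint")
        if self.conflict_accessions & (self.client_accessions | self.upregulated_accessions):
            raise ValueError("conflict set must be disjoint from client/upregulated sets")

    def null_accessions(self, proteins: list[str]) -> set[str]:
        planted = self.client_accessions | self.upregulated_accessions | self.conflict_accessions
        return set(proteins) - planted


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, n: int, fraction: float, exact: bool) -> int:
    if exact:
        return int(round(n * fraction))
    return int(rng.binomial(n, fraction))


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str = MIXED) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _sequence_for(rng: np.random.Generator, ann_length: int,
                  sp_range: tuple[int, int] | None,
                  tmh_ranges: tuple[tuple[int, int], ...]) -> str:
    seq = list(_random_sequence(rng, ann_length))
    seq[0] = "M"
    if sp_range is not None:
        s, e = sp_range
        # charged N-region, hydrophobic H-region, polar C-region
        h_start = s + 2
        h_end = max(h_start + 7, e - 3)
        for i in range(s, min(h_start - 1, e)):
            seq[i] = rng.choice(list(CHARGED_POS))
        for i in range(h_start - 1, min(h_end, e)):
            seq[i] = rng.choice(list(HYDROPHOBIC))
        for i in range(h_end, e):
            seq[i] = rng.choice(list(POLAR))
        seq[0] = "M"
    for ts, te in tmh_ranges:
        for i in range(ts - 1, te):
            seq[i] = rng.choice(list(HYDROPHOBIC))
    return "".join(seq)


def _place_tmhs(rng: np.random.Generator, cls: str, length: int,
                sp_end: int | None) -> tuple[tuple[int, int], ...]:
    """Place TMH intervals consistent with the sampled membrane class."""
    span = int(rng.integers(19, 24))
    lo = (sp_end or 0) + 10
    if cls == "tail_anchored":
        end = length - int(rng.integers(3, 15))
        return ((max(lo, end - span + 1), end),)
    if cls in ("type_I", "single_span_no_sp"):
        # keep clear of the C-terminal tail window so the class is unambiguous
        hi = length - span - 31
        start = int(rng.integers(lo, max(lo + 1, hi)))
        return ((start, start + span - 1),)
    if cls == "hairpin":
        start = int(rng.integers(lo, max(lo + 1, length - 60)))
        return ((start, start + span - 1), (start + span + 5, start + 2 * span + 4))
    if cls == "multi_spanning":
        n_tmh = int(rng.integers(2, 9))
        gaps = rng.integers(8, 40, size=n_tmh)
        ranges = []
        pos = lo
        for g in gaps:
            start = pos + int(g)
            end = start + span - 1
            if end > length - 35:
                break
            ranges.append((start, end))
            pos = end
        if len(ranges) < 2:  # cramped protein: force two adjacent helices
            ranges = [(lo, lo + span - 1), (lo + span + 8, lo + 2 * span + 7)]
        return tuple(ranges)
    raise ValueError(f"unknown membrane class {cls}")


def generate_annotations(
    proteins: list[str],
    config: TruthConfig,
    rng: np.random.Generator,
) -> dict[str, ProteinAnnotation]:
    """Draw annotations matching the configured SP/N-glyc/membrane fractions."""
    n = len(proteins)
    n_membrane = _draw_counts(rng, n, config.membrane_fraction, config.exact_counts)
    order = rng.permutation(n)
    membrane_idx = list(order[:n_membrane])
    rest = list(order[n_membrane:])

    # membrane classes
    classes = list(MEMBRANE_CLASS_SHARES)
    probs = np.array([MEMBRANE_CLASS_SHARES[c] for c in classes])
    membrane_cls = {i: classes[k] for i, k in zip(membrane_idx, rng.choice(len(classes), size=n_membrane, p=probs))}

    # soluble SP proteins cover the SP fraction not taken by type I
    n_sp_total = _draw_counts(rng, n, config.sp_fraction, config.exact_counts)
    n_type_i = sum(1 for c in membrane_cls.values() if c == "type_I")
    n_soluble_sp = max(0, n_sp_total - n_type_i)
    soluble_sp_idx = set(rest[:n_soluble_sp])

    secretory = set(membrane_idx) | soluble_sp_idx
    f_sec = max(len(secretory) / n, 1e-9)
    # glyco probability 4x higher among secretory proteins, matching overall target
    p_other = min(1.0, config.nglyc_fraction / (1 + 3 * f_sec))
    p_sec = min(1.0, 4 * p_other)

    annotations: dict[str, ProteinAnnotation] = {}
    for i, acc in enumerate(proteins):
        length = int(rng.integers(120, 800))
        sp_range = None
        tmh_ranges: tuple[tuple[int, int], ...] = ()
        hairpin = False
        if i in membrane_cls:
            cls = membrane_cls[i]
            if cls == "type_I":
                sp_range = (1, int(rng.integers(16, 31)))
            hairpin = cls == "hairpin"
            tmh_ranges = _place_tmhs(rng, cls, length, sp_range[1] if sp_range else None)
        elif i in soluble_sp_idx:
            sp_range = (1, int(rng.integers(16, 31)))

        is_secretory = i in secretory
        glyc: tuple[int, ...] = ()
        if rng.random() < (p_sec if is_secretory else p_other):
            lo = (sp_range[1] if sp_range else 0) + 1
            glyc = (int(rng.integers(lo, length + 1)),)

        if is_secretory:
            compartments = (str(rng.choice(ENDO_EXO_COMPARTMENTS)),)
        else:
            pool = ENDO_EXO_COMPARTMENTS if rng.random() < 0.115 else OTHER_COMPARTMENTS
            compartments = (str(rng.choice(pool)),)

        sequence = _sequence_for(rng, length, sp_range, tmh_ranges)
        annotations[acc] = ProteinAnnotation(
            accession=acc,
            gene=f"GENE{i + 1}",
            length=length,
            sp_range=sp_range,
            tmh_ranges=tmh_ranges,
            n_glyc_sites=glyc,
            hairpin=hairpin,
            compartments=compartments,
            sequence=sequence,
        )
    return annotations


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _make_design(n_replicates: int, n_experiments: int) -> list[SampleDesign]:
    samples = []
    for exp in range(1, n_experiments + 1):
        for group in ("control", "sirna1", "sirna2"):
            for rep in range(1, n_replicates + 1):
                samples.append(SampleDesign(
                    name=f"{group}_e{exp}_r{rep}", group=group,
                    replicate=rep, experiment=exp,
                ))
    return samples


def generate_cohort(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    n_experiments: int = 1,
    config: TruthConfig | None = None,
    seed: int = 0,
) -> tuple[LfqCohort, dict[str, ProteinAnnotation], SyntheticTruth]:
    """Generate one knockdown cohort with annotations and a truth ledger.

    All randomness flows from a single generator seeded with ``seed``, so
    identical arguments give bit-identical cohorts.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    config = config or TruthConfig()
    rng = np.random.default_rng(seed)
    proteins = [f"SYN{i + 1:05d}" for i in range(n_proteins)]

    annotations = generate_annotations(proteins, config, rng)

    # planted effect sets: clients must carry a targeting signal so that the
    # client-profile stage has structure to recover
    n_clients = _draw_counts(rng, n_proteins, config.client_fraction, config.exact_counts)
    n_up = _draw_counts(rng, n_proteins, config.upregulated_fraction, config.exact_counts)
    n_conflict = _draw_counts(rng, n_proteins, config.conflict_fraction, config.exact_counts)
    signal_bearing = [p for p in proteins if annotations[p].is_client_type]
    n_clients = min(n_clients, len(signal_bearing))
    client_acc = (
        {str(p) for p in rng.choice(signal_bearing, size=n_clients, replace=False)}
        if n_clients else set()
    )
    remaining = [p for p in proteins if p not in client_acc]
    picked = [str(p) for p in
              rng.choice(remaining, size=min(n_up + n_conflict, len(remaining)), replace=False)]
    up_acc = set(picked[:n_up])
    conflict_acc = set(picked[n_up:])

    effect1 = {p: 0.0 for p in proteins}
    effect2 = {p: 0.0 for p in proteins}
    for p in client_acc:
        effect1[p] = config.effect_log2
        effect2[p] = config.effect_log2 * config.sirna2_attenuation
    for p in up_acc:
        effect1[p] = config.upregulated_effect_log2
        effect2[p] = config.upregulated_effect_log2 * config.sirna2_attenuation
    for p in conflict_acc:
        effect1[p] = config.effect_log2
        effect2[p] = -config.effect_log2

    samples = _make_design(n_replicates, n_experiments)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_proteins)
    exp_intercept = rng.normal(0.0, config.experiment_sd_log2, size=n_experiments)

    log2 = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        if s.group == "sirna1":
            eff = np.array([effect1[p] for p in proteins])
        elif s.group == "sirna2":
            eff = np.array([effect2[p] for p in proteins])
        else:
            eff = 0.0
        noise = rng.normal(0.0, config.noise_sd_log2, size=n_proteins) if config.noise_sd_log2 > 0 else 0.0
        log2[:, j] = baseline + exp_intercept[s.experiment - 1] + eff + noise

    intensity = np.exp2(log2)

    # MNAR: logistic in log2 intensity below the low-intensity threshold
    miss = np.zeros(log2.shape, dtype=bool)
    if config.mnar_slope > 0:
        p_mnar = 1.0 / (1.0 + np.exp(config.mnar_slope * (log2 - config.mnar_threshold_log2)))
        miss |= rng.random(log2.shape) < p_mnar
    if config.mcar_rate > 0:
        miss |= rng.random(log2.shape) < config.mcar_rate
    intensity[miss] = np.nan

    cohort = LfqCohort(proteins=proteins, samples=samples, intensity=intensity,
                       meta={"synthetic_seed": seed})
    truth = SyntheticTruth(
        client_accessions=client_acc,
        upregulated_accessions=up_acc,
        conflict_accessions=conflict_acc,
        effect_log2=effect1,
        effect_log2_sirna2=effect2,
        baseline_log2_mean=config.baseline_log2_mean,
        baseline_log2_sd=config.baseline_log2_sd,
        noise_sd_log2=config.noise_sd_log2,
        missingness=(config.mnar_slope, config.mcar_rate),
        seed=seed,
        config=config,
    )
    logger.info(
        "generated cohort: %d proteins, %d clients, %d upregulated, %d conflict decoys",
        n_proteins, len(client_acc), len(up_acc), len(conflict_acc),
    )
    return cohort, annotations, truth


def generate_null_cohort(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    seed: int = 0,
    config: TruthConfig | None = None,
) -> LfqCohort:
    """A cohort with no planted effects (FDR-calibration fixture)."""
    base = config or TruthConfig()
    null_config = replace(base, client_fraction=0.0, upregulated_fraction=0.0,
                          conflict_fraction=0.0)
    cohort, _, _ = generate_cohort(n_proteins, n_replicates, 1, null_config, seed)
    return cohort


# ---------------------------------------------------------------------------
# sequences for the translation-speed stage
# ---------------------------------------------------------------------------

def generate_codon_rate_table(seed: int = 0) -> CodonRateTable:
    """A synthetic codon elongation-rate table (uniform 2-15 codons/s).

    Stands in, clearly labelled as synthetic, for experimentally derived
    codon-specific elongation rates when none are supplied.
    """
    rng = np.random.default_rng(seed)
    from .scales import SENSE_CODONS
    return CodonRateTable({c: float(r) for c, r in
                           zip(SENSE_CODONS, rng.uniform(2.0, 15.0, size=len(SENSE_CODONS)))})


def generate_cds(
    annotations: Mapping[str, ProteinAnnotation],
    seed: int = 0,
) -> dict[str, str]:
    """Reverse-translate each protein sequence into a CDS with random
    synonymous codons plus a stop codon (consistent with the annotation)."""
    rng = np.random.default_rng(seed)
    cds: dict[str, str] = {}
    for acc, ann in annotations.items():
        if ann.sequence is None:
            continue
        codons = [str(rng.choice(CODONS_BY_RESIDUE[aa])) for aa in ann.sequence]
        codons[0] = "ATG"  # sequences start with Met
        codons.append(str(rng.choice(("TAA", "TAG", "TGA"))))
        cds[acc] = "".join(codons)
    return cds


def write_cohort_dir(
    out_dir: str | Path,
    cohort: LfqCohort,
    annotations: Mapping[str, ProteinAnnotation],
    truth: SyntheticTruth | None = None,
    cds: Mapping[str, str] | None = None,
    rates: CodonRateTable | None = None,
) -> Path:
    """Emit the cohort in the same text formats :mod:`erclients.proteome_io`
    reads (LFQ TSV + design TSV + annotation TSV + FASTA + rate CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_lfq_table(cohort, out / "lfq.tsv", out / "design.tsv")
    pio.write_annotations(annotations, out / "annotations.tsv")
    pio.write_fasta({a: ann.sequence for a, ann in annotations.items() if ann.sequence},
                    out / "proteins.fasta")
    if cds is not None:
        pio.write_fasta(cds, out / "cds.fasta")
    if rates is not None:
        pio.write_codon_rates(rates, out / "codon_rates.csv")
    if truth is not None:
        with open(out / "truth.tsv", "w") as fh:
            fh.write("accession\trole\teffect_log2_sirna1\teffect_log2_sirna2\n")
            for acc in cohort.proteins:
                if acc in truth.client_accessions:
                    role = "client"
                elif acc in truth.upregulated_accessions:
                    role = "upregulated"
                elif acc in truth.conflict_accessions:
                    role = "conflict"
                else:
                    role = "null"
                fh.write(f"{acc}\t{role}\t{truth.effect_log2[acc]!r}\t"
                         f"{truth.effect_log2_sirna2[acc]!r}\n")
    return out


__all__ = [
    "SyntheticTruth", "TruthConfig", "generate_annotations", "generate_cds",
    "generate_codon_rate_table", "generate_cohort", "generate_null_cohort",
    "write_cohort_dir",
]
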