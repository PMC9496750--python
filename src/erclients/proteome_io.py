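"""Readers, writers and the validated in-memory data model.

External formats (all plain text):

* LFQ intensity table: tab-separated, one ``accession`` column plus one
  intensity column per sample, MaxQuant ``proteinGroups``-style dialect —
  an intensity of 0 (or an empty cell) means "not quantified", and rows
  whose accession starts with ``CON__`` or ``REV__`` are contaminant /
  decoy entries that are dropped (and counted).
* Sample design table: tab-separated with columns
  ``sample	group	replicate	experiment`` mapping intensity columns to the
  (group, replicate, experiment) triple; ``group`` is ``control``,
  ``sirna1`` or ``sirna2``.
* Annotation table: tab-separated with columns ``accession	gene	length
  sp	tmh	n_glyc	hairpin	compartments	sequence``; intervals are 1-based
  inclusive ``start-end`` (UniProt convention), ``tmh`` semicolon-delimited.
* FASTA (protein or CDS) via Biopython.
* Codon elongation-rate table: CSV with columns ``codon,rate`` in
  codons/second; all 61 sense codons must be present.

All genomic-style coordinates in this package are 1-based inclusive; every
writer states this in its header comment line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import SENSE_CODONS

logger = logging.getLogger(__name__)

GROUPS = ("control", "sirna1", "sirna2")
CONTAMINANT_PREFIXES = ("CON__", "REV__")

COORD_HEADER = "# coordinates are 1-based inclusive (UniProt convention)"


class FormatError(ValueError):
    """A file violated the documented dialect or an invariant."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """One MS sample: treatment group, replicate and experiment index."""

    name: str
    group: str
    replicate: int
    experiment: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r} for sample {self.name!r}")
        if self.replicate < 1 or self.experiment < 1:
            raise FormatError(f"replicate/experiment indices must be >= 1 ({self.name!r})")

    @property
    def triple(self) -> tuple[str, int, int]:
        return (self.group, self.replicate, self.experiment)


@dataclass
class LfqCohort:
    """Protein x sample matrix of linear-scale LFQ intensities.

    Missing values are ``NaN``; observed values are strictly positive.
    """

    proteins: list[str]
    samples: list[SampleDesign]
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.proteins), len(self.samples)):
            raise FormatError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.samples)} samples"
            )
        if len(set(self.proteins)) != len(self.proteins):
            dupes = [p for p in set(self.proteins) if self.proteins.count(p) > 1]
            raise FormatError(f"duplicate protein identifiers: {sorted(dupes)[:5]}")
        triples = [s.triple for s in self.samples]
        if len(set(triples)) != len(triples):
            raise FormatError("duplicate (group, replicate, experiment) triples in design")
        groups = {s.group for s in self.samples}
        if "control" not in groups:
            raise FormatError("cohort has no control samples")
        if not groups & {"sirna1", "sirna2"}:
            raise FormatError("cohort has no targeting-siRNA samples")
        observed = self.intensity[~np.isnan(self.intensity)]
        if observed.size and observed.min() <= 0:
            raise FormatError("observed intensities must be > 0 (0 means missing)")

    # -- convenience accessors -------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if any(s.group == g for s in self.samples))

    @property
    def experiments(self) -> tuple[int, ...]:
        return tuple(sorted({s.experiment for s in self.samples}))

    def sample_index(self, group: str | None = None, experiment: int | None = None) -> np.ndarray:
        """Column indices of samples matching the given group/experiment."""
        idx = [
            j for j, s in enumerate(self.samples)
            if (group is None or s.group == group)
            and (experiment is None or s.experiment == experiment)
        ]
        return np.asarray(idx, dtype=int)

    def log2_intensity(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log2(self.intensity)

    def subset(self, proteins: Iterable[str]) -> "LfqCohort":
        keep = set(proteins)
        rows = [i for i, p in enumerate(self.proteins) if p in keep]
        return LfqCohort(
            proteins=[self.proteins[i] for i in rows],
            samples=list(self.samples),
            intensity=self.intensity[rows, :].copy(),
            meta=dict(self.meta),
        )

    def with_intensity(self, intensity: np.ndarray) -> "LfqCohort":
        return LfqCohort(
            proteins=list(self.proteins),
            samples=list(self.samples),
            intensity=np.asarray(intensity, dtype=float),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ProteinAnnotation:
    """Structural/topology metadata for one protein (UniProt-derived)."""

    accession: str
    gene: str
    length: int
    sp_range: tuple[int, int] | None = None
    tmh_ranges: tuple[tuple[int, int], ...] = ()
    n_glyc_sites: tuple[int, ...] = ()
    hairpin: bool = False
    compartments: tuple[str, ...] = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FormatError(f"{self.accession}: length must be >= 1")
        if self.sp_range is not None:
            s, e = self.sp_range
            if s != 1:
                raise FormatError(f"{self.accession}: SP must start at residue 1")
            if not (1 <= s <= e <= self.length):
                raise FormatError(f"{self.accession}: SP {self.sp_range} outside [1, {self.length}]")
        prev_end = 0
        for s, e in self.tmh_ranges:
            if not (1 <= s <= e <= self.length):
                raise FormatError(f"{self.accession}: TMH {s}-{e} outside [1, {self.length}]")
            if s <= prev_end:
                raise FormatError(f"{self.accession}: TMH ranges unsorted or overlapping")
            prev_end = e
        for pos in self.n_glyc_sites:
            if not (1 <= pos <= self.length):
                raise FormatError(f"{self.accession}: glyco site {pos} outside [1, {self.length}]")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise FormatError(
                f"{self.accession}: sequence length {len(self.sequence)} != length {self.length}"
            )

    @property
    def has_sp(self) -> bool:
        return self.sp_range is not None

    @property
    def n_tmh(self) -> int:
        return len(self.tmh_ranges)

    @property
    def is_client_type(self) -> bool:
        """Carries a targeting signal: cleavable SP or at least one TMH."""
        return self.has_sp or self.n_tmh > 0

    def sp_sequence(self) -> str | None:
        if self.sequence is None or self.sp_range is None:
            return None
        return self.sequence[self.sp_range[0] - 1:self.sp_range[1]]

    def tmh_sequences(self) -> list[str]:
        if self.sequence is None:
            return []
        return [self.sequence[s - 1:e] for s, e in self.tmh_ranges]


@dataclass(frozen=True)
class CodonRateTable:
    """Codon-specific elongation rates in codons/second."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        normalized = {c.upper(): float(r) for c, r in self.rates.items()}
        missing = [c for c in SENSE_CODONS if c not in normalized]
        if missing:
            raise FormatError(f"rate table lacks sense codons: {missing}")
        bad = [c for c, r in normalized.items() if not np.isfinite(r) or r <= 0]
        if bad:
            raise FormatError(f"rates must be finite and positive; bad codons: {sorted(bad)}")
        object.__setattr__(self, "rates", normalized)

    def __getitem__(self, codon: str) -> float:
        return self.rates[codon.upper()]

    def __contains__(self, codon: str) -> bool:
        return codon.upper() in self.rates


# ---------------------------------------------------------------------------
# LFQ table + design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "group", "replicate", "experiment"}
    if not required.issubset(df.columns):
        raise FormatError(f"design table needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        SampleDesign(
            name=row["sample"],
            group=row["group"],
            replicate=int(row["replicate"]),
            experiment=int(row["experiment"]),
        )
        for _, row in df.iterrows()
    ]


def write_design(samples: Sequence[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\treplicate\texperiment\n")
        for s in samples:
            fh.write(f"{s.name}\t{s.group}\t{s.replicate}\t{s.experiment}\n")


def read_lfq_table(path: str | Path, design_path: str | Path) -> LfqCohort:
    """Read a MaxQuant-dialect LFQ table plus its sample design.

    Zeros and blank cells become missing (NaN); ``CON__``/``REV__`` rows are
    dropped and counted in ``cohort.meta['dropped_contaminants']``.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"accession": str})
    if "accession" not in df.columns:
        raise FormatError(f"{path}: LFQ table needs an 'accession' column")
    for s in design:
        if s.name not in df.columns:
            raise FormatError(f"{path}: design sample column {s.name!r} not in LFQ table")
    extra = [c for c in df.columns if c != "accession" and c not in {s.name for s in design}]
    if extra:
        raise FormatError(f"{path}: unmapped sample columns {extra}")

    mask = df["accession"].str.startswith(CONTAMINANT_PREFIXES)
    n_dropped = int(mask.sum())
    if n_dropped:
        logger.info("dropped %d contaminant/reverse rows from %s", n_dropped, path)
    df = df.loc[~mask]
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise FormatError(f"{path}: duplicate protein IDs {dupes[:5]}")

    matrix = df[[s.name for s in design]].to_numpy(dtype=float)
    matrix[matrix == 0.0] = np.nan  # MaxQuant dialect: 0 means not quantified
    cohort = LfqCohort(
        proteins=df["accession"].tolist(),
        samples=design,
        intensity=matrix,
        meta={"dropped_contaminants": n_dropped, "source": str(path)},
    )
    logger.info("read cohort: %d proteins x %d samples", cohort.n_proteins, len(design))
    return cohort


def write_lfq_table(cohort: LfqCohort, path: str | Path, design_path: str | Path | None = None) -> None:
    """Write the cohort back in the MaxQuant dialect (missing -> 0).

    Round-trips bit-exactly through :func:`read_lfq_table` (floats are
    written with ``repr`` precision).
    """
    with open(path, "w") as fh:
        fh.write("# LFQ intensities, linear scale; 0 = not quantified\n")
        fh.write("accession\t" + "\t".join(s.name for s in cohort.samples) + "\n")
        for i, acc in enumerate(cohort.proteins):
            cells = [
                "0" if np.isnan(v) else repr(float(v))
                for v in cohort.intensity[i]
            ]
            fh.write(acc + "\t" + "\t".join(cells) + "\n")
    if design_path is not None:
        write_design(cohort.samples, design_path)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_interval(text: str) -> tuple[int, int]:
    s, _, e = text.partition("-")
    return int(s), int(e)


def parse_annotation_row(row: Mapping[str, str]) -> ProteinAnnotation:
    """Build one validated annotation from a TSV row (raises on invariants)."""
    def cell(key: str) -> str:
        v = row.get(key, "")
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()

    sp = cell("sp")
    tmh = cell("tmh")
    glyc = cell("n_glyc")
    seq = cell("sequence")
    return ProteinAnnotation(
        accession=cell("accession"),
        gene=cell("gene"),
        length=int(cell("length")),
        sp_range=_parse_interval(sp) if sp else None,
        tmh_ranges=tuple(_parse_interval(t) for t in tmh.split(";") if t.strip()),
        n_glyc_sites=tuple(int(g) for g in glyc.split(";") if g.strip()),
        hairpin=cell("hairpin").lower() in {"1", "true", "yes"},
        compartments=tuple(c.strip() for c in cell("compartments").split(";") if c.strip()),
        sequence=seq or None,
    )


def read_annotations(
    path: str | Path,
    rejected: list[tuple[str, str]] | None = None,
) -> dict[str, ProteinAnnotation]:
    """Read the annotation table; malformed rows are rejected with a logged
    reason (and appended to ``rejected`` as (accession, reason) if given)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "accession" not in df.columns or "length" not in df.columns:
        raise FormatError(f"{path}: annotation table needs 'accession' and 'length' columns")
    annotations: dict[str, ProteinAnnotation] = {}
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            ann = parse_annotation_row(row)
        except (FormatError, ValueError) as exc:
            n_rejected += 1
            acc = str(row.get("accession", "?"))
            logger.warning("rejected annotation row %s: %s", acc, exc)
            if rejected is not None:
                rejected.append((acc, str(exc)))
            continue
        annotations[ann.accession] = ann
    logger.info("read %d annotations (%d rows rejected) from %s", len(annotations), n_rejected, path)
    return annotations


def write_annotations(annotations: Mapping[str, ProteinAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        fh.write("accession\tgene\tlength\tsp\ttmh\tn_glyc\thairpin\tcompartments\tsequence\n")
        for ann in annotations.values():
            sp = f"{ann.sp_range[0]}-{ann.sp_range[1]}" if ann.sp_range else ""
            tmh = ";".join(f"{s}-{e}" for s, e in ann.tmh_ranges)
            glyc = ";".join(str(g) for g in ann.n_glyc_sites)
            fh.write(
                f"{ann.accession}\t{ann.gene}\t{ann.length}\t{sp}\t{tmh}\t{glyc}\t"
                f"{'true' if ann.hairpin else 'false'}\t{';'.join(ann.compartments)}\t"
                f"{ann.sequence or ''}\n"
            )


# ---------------------------------------------------------------------------
# FASTA and codon rates
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_codon_rates(path: str | Path) -> CodonRateTable:
    """Read a ``codon,rate`` CSV; completeness over the 61 sense codons is
    enforced by :class:`CodonRateTable` (missing codons are listed)."""
    rates: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if "codon" not in row or "rate" not in row:
                raise FormatError(f"{path}: codon-rate CSV needs 'codon' and 'rate' columns")
            rates[row["codon"].strip().upper()] = float(row["rate"])
    return CodonRateTable(rates)


def write_codon_rates(table: CodonRateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon,rate\n")
        for codon in SENSE_CODONS:
            fh.write(f"{codon},{table[codon]!r}\n")


__all__ = [
    "CodonRateTable", "FormatError", "LfqCohort", "ProteinAnnotation",
    "SampleDesign", "parse_annotation_row", "read_annotations",
    "read_codon_rates", "read_design", "read_fasta", "read_lfq_table",
    "write_annotations", "write_codon_rates", "write_design", "write_fasta",
    "write_lfq_table",
]
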