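"""Client catalogues: membrane-protein classes, TMH positions, enrichment.

A "client" of a targeting pathway is a protein whose steady-state abundance
drops upon depletion of that pathway's receptor and that carries a
targeting signal — a cleavable signal peptide (SP) or at least one
transmembrane helix (TMH).  Clients are classified by signal architecture:

* ``soluble_sp``      — SP, no TMH
* ``type_I``          — SP plus a single TMH
* ``single_span_no_sp`` — one TMH, no SP, not at the extreme C-terminus
  (type II/III membrane proteins; the orientation needed to tell them
  apart is usually absent from annotation tables, so both collapse here)
* ``tail_anchored``   — one TMH ending within ``tail_window`` residues of
  the C-terminus, no SP (type IV)
* ``hairpin``         — monotopic hairpin flag set
* ``multi_spanning``  — two or more TMHs (with or without SP)

The location of the first TMH is summarized as the position of its central
residue in percent of the protein length, binned into N-terminal [0, 25],
central (25, 75) and C-terminal [75, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import ProteinAnnotation

logger = logging.getLogger(__name__)

CLIENT_CLASSES = (
    "soluble_sp", "type_I", "single_span_no_sp", "tail_anchored",
    "hairpin", "multi_spanning",
)
POSITION_BINS = ("n_terminal", "central", "c_terminal")

DEFAULT_TAIL_WINDOW = 30


@dataclass(frozen=True)
class ClientRecord:
    """One pathway client with its targeting-signal profile."""

    accession: str
    pathway: str
    client_class: str
    has_sp: bool
    n_glycosylated: bool
    first_tmh_rel_pos: float | None = None
    position_bin: str | None = None

    def __post_init__(self) -> None:
        if self.client_class not in CLIENT_CLASSES:
            raise ValueError(f"unknown client class {self.client_class!r}")
        if (self.first_tmh_rel_pos is None) != (self.position_bin is None):
            raise ValueError("position_bin defined iff first_tmh_rel_pos defined")


def classify_membrane_protein(
    annotation: ProteinAnnotation,
    tail_window: int = DEFAULT_TAIL_WINDOW,
) -> str:
    """Classify a client by SP presence and TMH count/location."""
    if not annotation.is_client_type:
        raise ValueError(f"{annotation.accession} carries no targeting signal (not a client)")
    if annotation.hairpin:
        return "hairpin"
    n_tmh = annotation.n_tmh
    if annotation.has_sp:
        if n_tmh == 0:
            return "soluble_sp"
        if n_tmh == 1:
            return "type_I"
        return "multi_spanning"
    if n_tmh >= 2:
        return "multi_spanning"
    # single TMH, no SP
    _, tmh_end = annotation.tmh_ranges[0]
    if annotation.length - tmh_end <= tail_window:
        return "tail_anchored"
    return "single_span_no_sp"


def first_tmh_relative_position(annotation: ProteinAnnotation) -> float:
    """Central residue of the first TMH in percent of the protein length.

    100 * ((start + end) / 2) / length; the fractional value is kept.
    """
    if annotation.n_tmh == 0:
        raise ValueError(f"{annotation.accession} has no TMH")
    start, end = annotation.tmh_ranges[0]
    return 100.0 * ((start + end) / 2.0) / annotation.length


def bin_position(percent: float) -> str:
    """[0, 25] -> n_terminal; (25, 75) -> central; [75, 100] -> c_terminal."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"relative position {percent} outside [0, 100]")
    if percent <= 25.0:
        return "n_terminal"
    if percent < 75.0:
        return "central"
    return "c_terminal"


def build_client_records(
    accessions: Iterable[str],
    annotations: Mapping[str, ProteinAnnotation],
    pathway: str,
    tail_window: int = DEFAULT_TAIL_WINDOW,
) -> list[ClientRecord]:
    """Turn affected accessions into client records; proteins without a
    targeting signal are skipped (logged) — they are secondary effects,
    not pathway clients."""
    records = []
    n_skipped = 0
    for acc in accessions:
        ann = annotations.get(acc)
        if ann is None or not ann.is_client_type:
            n_skipped += 1
            continue
        pos = first_tmh_relative_position(ann) if ann.n_tmh else None
        records.append(ClientRecord(
            accession=acc,
            pathway=pathway,
            client_class=classify_membrane_protein(ann, tail_window),
            has_sp=ann.has_sp,
            n_glycosylated=bool(ann.n_glyc_sites),
            first_tmh_rel_pos=pos,
            position_bin=bin_position(pos) if pos is not None else None,
        ))
    if n_skipped:
        logger.info("pathway %s: %d affected proteins without targeting signal skipped",
                    pathway, n_skipped)
    return records


@dataclass(frozen=True)
class PositionSummary:
    """Mean +/- sd of the first-TMH relative position plus bin fractions."""

    mean: float
    sd: float
    bin_fractions: dict[str, float]
    n: int


def position_summary(clients: Sequence[ClientRecord]) -> PositionSummary:
    """Arithmetic mean and (population) sd of the first-TMH relative
    position over TMH-bearing clients; bin fractions sum to 1."""
    positions = [c.first_tmh_rel_pos for c in clients if c.first_tmh_rel_pos is not None]
    if not positions:
        raise ValueError("no TMH-bearing clients")
    arr = np.asarray(positions)
    bins = [c.position_bin for c in clients if c.position_bin is not None]
    fractions = {b: bins.count(b) / len(bins) for b in POSITION_BINS}
    return PositionSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        bin_fractions=fractions,
        n=len(positions),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of a feature among affected proteins, with the
    underlying fractions and a one-sided hypergeometric p."""

    fold: float | None
    fraction_affected: float
    fraction_background: float
    p_value: float
    k: int  # feature-positive among affected
    n: int  # affected
    K: int  # feature-positive in background
    N: int  # background


def enrichment_factor(
    feature_predicate: Callable[[ProteinAnnotation], bool],
    affected_set: Iterable[str],
    background_set: Iterable[str],
    annotations: Mapping[str, ProteinAnnotation],
) -> EnrichmentResult:
    """Fold = (feature fraction among affected) / (feature fraction among
    background); background must contain the affected set.  The p-value is
    a plain one-sided hypergeometric over-representation test."""
    affected = set(affected_set)
    background = set(background_set)
    if not affected or not background:
        raise ValueError("affected and background sets must be non-empty")
    if not affected <= background:
        raise ValueError("background set must contain the affected set")
    has = {acc for acc in background if acc in annotations and feature_predicate(annotations[acc])}
    k = len(affected & has)
    n = len(affected)
    K = len(has)
    N = len(background)
    frac_affected = k / n
    frac_background = K / N
    fold = None if frac_background == 0 else frac_affected / frac_background
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(fold, frac_affected, frac_background, p, k, n, K, N)


def compartment_composition(
    accessions: Iterable[str],
    annotations: Mapping[str, ProteinAnnotation],
) -> dict[str, float]:
    """Fraction per compartment category over proteins with at least one
    category; multi-category proteins count once, by their first listed
    (primary) category."""
    primary = [
        annotations[acc].compartments[0]
        for acc in accessions
        if acc in annotations and annotations[acc].compartments
    ]
    if not primary:
        return {}
    total = len(primary)
    return {cat: primary.count(cat) / total for cat in sorted(set(primary))}


def double_kd_specific(
    clients_double: Iterable[str],
    clients_single_a: Iterable[str],
    clients_single_b: Iterable[str],
) -> set[str]:
    """Clients of the double depletion not already seen in either single
    depletion — the double-knockdown-specific (both-pathway) client set."""
    return set(clients_double) - (set(clients_single_a) | set(clients_single_b))


def pool_clients(
    single_clients: Iterable[str],
    double_specific_clients: Iterable[str],
) -> set[str]:
    """Union of single-depletion clients and double-knockdown-specific
    clients, deduplicated by accession."""
    return set(single_clients) | set(double_specific_clients)


def client_table(records: Sequence[ClientRecord]) -> pd.DataFrame:
    """Flat per-client table (one row per client record)."""
    return pd.DataFrame(
        [
            {
                "accession": c.accession,
                "pathway": c.pathway,
                "client_class": c.client_class,
                "has_sp": c.has_sp,
                "n_glycosylated": c.n_glycosylated,
                "first_tmh_rel_pos": c.first_tmh_rel_pos,
                "position_bin": c.position_bin,
            }
            for c in records
        ]
    )


__all__ = [
    "CLIENT_CLASSES", "ClientRecord", "EnrichmentResult", "PositionSummary",
    "bin_position", "build_client_records", "classify_membrane_protein",
    "client_table", "compartment_composition", "double_kd_specific",
    "enrichment_factor", "first_tmh_relative_position", "pool_clients",
    "position_summary",
]
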