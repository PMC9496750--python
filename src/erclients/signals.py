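"""Targeting-signal feature metrics.

Per-sequence metrics (all length-normalized where averaged):

* Kyte-Doolittle hydrophobicity — mean hydropathy over the sequence.
* GP content — fraction of glycine plus proline residues.
* Zimmerman polarity — mean polarity over the sequence.
* Net charge — +1 per Lys/Arg, -1 per Asp/Glu; His and the chain termini
  contribute 0 (both choices configurable).
* dG_app — apparent free energy of translocon-mediated membrane insertion
  of a helix, from the position-dependent biological-hydrophobicity model
  (per-residue Gaussian profiles, aromatic interface terms for Trp/Tyr, a
  hydrophobic-moment term and a quadratic length correction); negative
  values favor insertion.  Units: kcal/mol.
* Signal-peptide segmentation into the charged N-region, hydrophobic
  H-region and polar C-region.  The packaged segmenter is a documented
  heuristic stand-in for HMM-based predictors (maximal-scoring
  Kyte-Doolittle window, extended while per-residue hydropathy stays
  positive); precomputed segmentations can be ingested instead, and the
  derived features (N-region net charge, H-region hydrophobicity and
  length, C-region polarity) are computed identically either way.
* Translation time of the N-terminal 80 codons from codon-specific
  elongation rates: rates are inverted and summed over the first
  min(240, len) nucleotides of the CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import CodonRateTable, ProteinAnnotation
from .scales import (
    AMINO_ACIDS,
    DG_C0,
    DG_C1,
    DG_C2,
    DG_C3,
    DG_MAX_LENGTH,
    DG_MIN_LENGTH,
    DG_PROFILES,
    KYTE_DOOLITTLE,
    RESIDUE_CHARGE,
    STOP_CODONS,
    ZIMMERMAN_POLARITY,
)

logger = logging.getLogger(__name__)

STANDARD_AA = set(AMINO_ACIDS)


class SegmentationError(ValueError):
    """The heuristic segmenter found no hydrophobic core (flagged, not fatal)."""


def _clean(seq: str, permissive: bool = False) -> str:
    """Validate/normalize an amino-acid string; nonstandard letters are a
    hard error by default, or skipped with a logged count when permissive."""
    seq = seq.upper()
    bad = [a for a in seq if a not in STANDARD_AA]
    if bad:
        if not permissive:
            raise ValueError(f"nonstandard residues {sorted(set(bad))} in sequence")
        logger.warning("skipping %d nonstandard residues", len(bad))
        seq = "".join(a for a in seq if a in STANDARD_AA)
    if not seq:
        raise ValueError("empty sequence")
    return seq


# ---------------------------------------------------------------------------
# scalar per-sequence metrics
# ---------------------------------------------------------------------------

def kd_hydrophobicity(seq: str, permissive: bool = False) -> float:
    """Mean Kyte-Doolittle hydropathy over the sequence."""
    seq = _clean(seq, permissive)
    return float(np.mean([KYTE_DOOLITTLE[a] for a in seq]))


def gp_content(seq: str, permissive: bool = False) -> float:
    """Fraction of Gly + Pro residues."""
    seq = _clean(seq, permissive)
    return (seq.count("G") + seq.count("P")) / len(seq)


def zimmerman_polarity(seq: str, permissive: bool = False) -> float:
    """Mean Zimmerman polarity over the sequence."""
    seq = _clean(seq, permissive)
    return float(np.mean([ZIMMERMAN_POLARITY[a] for a in seq]))


def net_charge(seq: str, permissive: bool = False,
               histidine_charge: float = 0.0) -> float:
    """Signed charge sum: +1 per K/R, -1 per D/E; His contributes
    ``histidine_charge`` (default 0) and termini are excluded."""
    seq = _clean(seq, permissive)
    charge = dict(RESIDUE_CHARGE, H=histidine_charge)
    return float(sum(charge.get(a, 0.0) for a in seq))


# ---------------------------------------------------------------------------
# dG_app membrane-insertion model
# ---------------------------------------------------------------------------

def _profile_contribution(aa: str, pos: float) -> float:
    prof = DG_PROFILES[aa]
    dg = prof[0] * np.exp(-prof[1] * pos * pos)
    if len(prof) == 5:  # Trp/Tyr aromatic interface Gaussians
        a2, a3, a4 = prof[2], prof[3], prof[4]
        dg += a2 * (np.exp(-a3 * (pos - a4) ** 2) + np.exp(-a3 * (pos + a4) ** 2))
    return float(dg)


def dg_app(tm_window: str, permissive: bool = False) -> float:
    """Apparent insertion free energy of one helix window, in kcal/mol.

    The window is scored exactly as given (no sliding-window length
    optimization): per-residue position-dependent contributions across the
    helix (positions scaled to [-9, 9]), plus the hydrophobic-moment term
    (100 degrees per residue) and the quadratic length correction.
    Supported lengths are ``DG_MIN_LENGTH``..``DG_MAX_LENGTH`` (9-40).
    """
    seq = _clean(tm_window, permissive)
    L = len(seq)
    if L < DG_MIN_LENGTH:
        raise ValueError(f"helix window of length {L} below minimum {DG_MIN_LENGTH}")
    if L > DG_MAX_LENGTH:
        raise ValueError(f"helix window of length {L} above maximum {DG_MAX_LENGTH}")
    contributions = np.empty(L)
    for i, aa in enumerate(seq):
        pos = 9.0 * (2.0 * (i + 1) - (L + 1)) / (L - 1)
        contributions[i] = _profile_contribution(aa, pos)
    angles = np.deg2rad(100.0 * np.arange(L))
    mu = np.hypot(np.sum(contributions * np.sin(angles)),
                  np.sum(contributions * np.cos(angles)))
    length_corr = DG_C1 + DG_C2 * L + DG_C3 * L * L
    return float(contributions.sum() + DG_C0 * mu + length_corr)


def dg_app_scan(sequence: str, min_len: int = 19, max_len: int = 23,
                permissive: bool = False) -> tuple[float, int, int]:
    """Optional scan mode: the lowest dG_app over all subwindows with
    lengths in [min_len, max_len]; returns (dG, start, end) 1-based."""
    seq = _clean(sequence, permissive)
    best: tuple[float, int, int] | None = None
    for L in range(min_len, min(max_len, len(seq)) + 1):
        for s in range(0, len(seq) - L + 1):
            dg = dg_app(seq[s:s + L])
            if best is None or dg < best[0]:
                best = (dg, s + 1, s + L)
    if best is None:
        raise ValueError(f"sequence shorter than min_len={min_len}")
    return best


# ---------------------------------------------------------------------------
# signal-peptide segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalFeatures:
    """SP segmentation plus the derived region features.

    Regions are 1-based inclusive intervals that tile the SP exactly once:
    N-region (charged), H-region (hydrophobic core), C-region (polar).
    """

    n_region: tuple[int, int]
    h_region: tuple[int, int]
    c_region: tuple[int, int] | None
    n_region_net_charge: float
    h_region_length: int
    h_region_hydrophobicity: float
    c_region_polarity: float | None

    def regions_cover(self, sp_length: int) -> bool:
        end = self.c_region[1] if self.c_region else self.h_region[1]
        contiguous = self.n_region[1] + 1 == self.h_region[0] and (
            self.c_region is None or self.h_region[1] + 1 == self.c_region[0]
        )
        return self.n_region[0] == 1 and end == sp_length and contiguous


def _features_from_regions(
    sp_seq: str,
    n_region: tuple[int, int],
    h_region: tuple[int, int],
    c_region: tuple[int, int] | None,
) -> SignalFeatures:
    n_seq = sp_seq[n_region[0] - 1:n_region[1]]
    h_seq = sp_seq[h_region[0] - 1:h_region[1]]
    c_seq = sp_seq[c_region[0] - 1:c_region[1]] if c_region else ""
    return SignalFeatures(
        n_region=n_region,
        h_region=h_region,
        c_region=c_region,
        n_region_net_charge=net_charge(n_seq) if n_seq else 0.0,
        h_region_length=len(h_seq),
        h_region_hydrophobicity=kd_hydrophobicity(h_seq),
        c_region_polarity=zimmerman_polarity(c_seq) if c_seq else None,
    )


def segment_sp(sp_seq: str, min_h_len: int = 6) -> SignalFeatures:
    """Heuristically segment a signal peptide into N/H/C regions.

    The H-region core is the maximal-scoring contiguous window of length
    ``min_h_len`` of summed Kyte-Doolittle hydropathy, extended in both
    directions while the per-residue hydropathy stays positive.  The first
    residue is always assigned to the N-region (the H-region starts at
    position 2 or later); the prefix is the N-region and the suffix the
    C-region.  Raises :class:`SegmentationError` when no positive-scoring
    hydrophobic core of the required length exists.
    """
    seq = _clean(sp_seq)
    if len(seq) < 8:
        raise ValueError(f"SP of length {len(seq)} too short to segment (need >= 8)")
    kd = np.array([KYTE_DOOLITTLE[a] for a in seq])
    # candidate cores start at position 2 (index 1): residue 1 is N-region
    scores = [
        (kd[s:s + min_h_len].sum(), s)
        for s in range(1, len(seq) - min_h_len + 1)
    ]
    best_score, best_start = max(scores, key=lambda t: (t[0], -t[1]))
    if best_score <= 0:
        raise SegmentationError("no positive-hydropathy window of required length")
    h_lo, h_hi = best_start, best_start + min_h_len - 1  # 0-based inclusive
    while h_lo > 1 and kd[h_lo - 1] > 0:
        h_lo -= 1
    while h_hi < len(seq) - 1 and kd[h_hi + 1] > 0:
        h_hi += 1
    n_region = (1, h_lo)
    h_region = (h_lo + 1, h_hi + 1)
    c_region = (h_hi + 2, len(seq)) if h_hi + 1 < len(seq) else None
    return _features_from_regions(seq, n_region, h_region, c_region)


def features_from_segmentation(
    sp_seq: str,
    n_end: int,
    h_end: int,
    c_end: int | None = None,
) -> SignalFeatures:
    """Ingest a precomputed segmentation (e.g. from an external predictor)
    given the 1-based end positions of the N- and H-regions; derived
    features are computed identically to the heuristic path."""
    seq = _clean(sp_seq)
    c_end = c_end or len(seq)
    if not 1 <= n_end < h_end <= c_end <= len(seq):
        raise ValueError(f"inconsistent segmentation ends ({n_end}, {h_end}, {c_end})")
    c_region = (h_end + 1, c_end) if h_end < c_end else None
    return _features_from_regions(seq, (1, n_end), (n_end + 1, h_end), c_region)


# ---------------------------------------------------------------------------
# translation speed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslationProfile:
    """Estimated translation time of the N-terminal CDS segment."""

    accession: str
    codons_used: tuple[str, ...]
    total_time: float  # seconds: sum of inverted elongation rates

    def __post_init__(self) -> None:
        if self.codons_used and not self.total_time > 0:
            raise ValueError("total_time must be > 0 for a non-empty codon list")


def translation_time(
    cds_seq: str,
    rate_table: CodonRateTable,
    accession: str = "",
    n_nucleotides: int = 240,
) -> TranslationProfile:
    """Sum of inverted codon elongation rates over the first
    min(``n_nucleotides``, len) nucleotides of the CDS (default 240 nt =
    80 codons).  A terminal stop codon inside the window is dropped; a
    trailing partial codon is dropped with a warning."""
    cds = cds_seq.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if not cds.startswith("ATG"):
        raise ValueError(f"CDS does not start with ATG ({cds[:3]})")
    head = cds[:min(n_nucleotides, len(cds))]
    if len(head) % 3:
        logger.warning("%s: trailing partial codon of %d nt dropped", accession, len(head) % 3)
        head = head[:len(head) - len(head) % 3]
    codons = [head[i:i + 3] for i in range(0, len(head), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    missing = sorted({c for c in codons if c not in rate_table})
    if missing:
        raise ValueError(f"codons absent from rate table: {missing}")
    total = float(sum(1.0 / rate_table[c] for c in codons))
    return TranslationProfile(accession=accession, codons_used=tuple(codons), total_time=total)


def rank_sum_compare(times_a: Sequence[float], times_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two distributions.

    For n_a + n_b <= 10 the exact two-sided p is computed by enumerating
    all label assignments (midranks for ties); larger samples use the
    tie-corrected normal approximation with continuity correction.
    Returns (Mann-Whitney U of sample a, p).
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    if na + nb <= 10:
        dev_obs = abs(u_obs - mu)
        total = comb(na + nb, na)
        n_extreme = 0
        for idx_a in combinations(range(na + nb), na):
            u = ranks[list(idx_a)].sum() - na * (na + 1) / 2.0
            if abs(u - mu) >= dev_obs - 1e-12:
                n_extreme += 1
        return u_obs, n_extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def signal_feature_table(
    annotations: Mapping[str, ProteinAnnotation],
    accessions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per annotated signal (SP or TMH) with the scalar metrics.

    dG_app is computed on the annotated span exactly; spans outside the
    supported 9-40 residue range get NaN.  SPs additionally carry the
    segmentation features when the heuristic finds a hydrophobic core.
    """
    rows = []
    for acc in (accessions if accessions is not None else annotations):
        ann = annotations.get(acc)
        if ann is None or ann.sequence is None:
            continue
        sp_seq = ann.sp_sequence()
        if sp_seq:
            row = {
                "accession": acc, "signal": "SP", "start": 1, "end": ann.sp_range[1],
                "kd_hydrophobicity": kd_hydrophobicity(sp_seq),
                "gp_content": gp_content(sp_seq),
                "polarity": zimmerman_polarity(sp_seq),
                "net_charge": net_charge(sp_seq),
                "dg_app": _safe_dg(sp_seq),
            }
            try:
                feats = segment_sp(sp_seq)
            except (SegmentationError, ValueError):
                logger.info("%s: SP segmentation undefined", acc)
            else:
                row.update({
                    "n_region_net_charge": feats.n_region_net_charge,
                    "h_region_length": feats.h_region_length,
                    "h_region_hydrophobicity": feats.h_region_hydrophobicity,
                    "c_region_polarity": feats.c_region_polarity,
                })
            rows.append(row)
        for k, tmh_seq in enumerate(ann.tmh_sequences()):
            s, e = ann.tmh_ranges[k]
            rows.append({
                "accession": acc, "signal": f"TMH{k + 1}", "start": s, "end": e,
                "kd_hydrophobicity": kd_hydrophobicity(tmh_seq),
                "gp_content": gp_content(tmh_seq),
                "polarity": zimmerman_polarity(tmh_seq),
                "net_charge": net_charge(tmh_seq),
                "dg_app": _safe_dg(tmh_seq),
            })
    return pd.DataFrame(rows)


def _safe_dg(seq: str) -> float:
    try:
        return dg_app(seq)
    except ValueError:
        return float("nan")


def translation_time_table(
    cds_map: Mapping[str, str],
    rate_table: CodonRateTable,
    accessions: Sequence[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for acc in (accessions if accessions is not None else cds_map):
        if acc not in cds_map:
            continue
        profile = translation_time(cds_map[acc], rate_table, accession=acc)
        rows.append({"accession": acc, "n_codons": len(profile.codons_used),
                     "total_time_s": profile.total_time})
    return pd.DataFrame(rows)


__all__ = [
    "SegmentationError", "SignalFeatures", "TranslationProfile", "dg_app",
    "dg_app_scan", "features_from_segmentation", "gp_content",
    "kd_hydrophobicity", "net_charge", "rank_sum_compare", "segment_sp",
    "signal_feature_table", "translation_time", "translation_time_table",
    "zimmerman_polarity",
]
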