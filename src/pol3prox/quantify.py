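"""ChIP-qPCR fold enrichment, condition ratios, blot normalization, and
count-table normalization.

The fold enrichment method: Ct values from the ChIP (IP) and mock
samples are first normalized against the TelVIR subtelomeric control
region, then against the input, and the mock-normalized exponentiated
double-difference is reported:

    dCt_s      = Ct_s(gene) - Ct_s(TelVIR)          for s in {IP, mock, input}
    FE         = E^-(dCt_IP - dCt_input) / E^-(dCt_mock - dCt_input)

with amplification efficiency E (2.0 = perfect doubling).  Mock
normalization is a division on the multiplicative fold scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import pooled_ttest
from .track_io import TELVIR, CountTable, CtTable

logger = logging.getLogger(__name__)

#: changes with p above this are flagged non-significant (the dot convention)
SIGNIFICANCE_ALPHA = 0.05


class QuantifyError(ValueError):
    pass


def fold_enrichment(
    ct: CtTable,
    gene: str,
    condition: str,
    replicate,
    efficiency: float = 2.0,
) -> float:
    """Fold enrichment of one gene in one replicate, TelVIR- and input-normalized."""
    if efficiency <= 0:
        raise QuantifyError(f"efficiency must be > 0, got {efficiency}")
    d = {}
    for kind in ("IP", "mock", "input"):
        d[kind] = ct.ct(kind, condition, gene, replicate) - ct.ct(
            kind, condition, TELVIR, replicate
        )
    ip_over_input = efficiency ** -(d["IP"] - d["input"])
    mock_over_input = efficiency ** -(d["mock"] - d["input"])
    return ip_over_input / mock_over_input


@dataclass
class EnrichmentEstimate:
    """Replicate-aggregated fold enrichment for one gene/condition.

    ``scatter`` is the (min, max) across replicates, the quantity plotted
    as error bars alongside the arithmetic mean; ``sd`` is available as
    an alternative.  ``p_value`` compares replicates against a named
    reference condition when one was supplied.
    """

    gene_id: str
    condition: str
    replicate_values: np.ndarray
    p_value: float | None = None
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        if self.replicate_values.size == 0 or np.any(self.replicate_values <= 0):
            raise QuantifyError("replicate fold enrichments must be positive")

    @property
    def mean(self) -> float:
        return float(self.replicate_values.mean())

    @property
    def scatter(self) -> tuple[float, float]:
        return float(self.replicate_values.min()), float(self.replicate_values.max())

    @property
    def sd(self) -> float:
        return float(self.replicate_values.std(ddof=1)) if self.replicate_values.size > 1 else 0.0

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= SIGNIFICANCE_ALPHA


def estimate_enrichment(
    ct: CtTable,
    gene: str,
    condition: str,
    efficiency: float = 2.0,
    reference_condition: str | None = None,
) -> EnrichmentEstimate:
    """Per-replicate fold enrichments aggregated into one estimate.

    With ``reference_condition`` set, a two-tailed Student's t-test
    compares the replicate fold enrichments between the two conditions.
    """
    values = np.array(
        [
            fold_enrichment(ct, gene, condition, rep, efficiency)
            for rep in ct.replicates(condition)
        ]
    )
    p = None
    if reference_condition is not None:
        ref = np.array(
            [
                fold_enrichment(ct, gene, reference_condition, rep, efficiency)
                for rep in ct.replicates(reference_condition)
            ]
        )
        p = pooled_ttest(values, ref).p_value
    return EnrichmentEstimate(gene, condition, values, p, reference_condition)


def enrichment_table(
    ct: CtTable,
    efficiency: float = 2.0,
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Tidy per-gene/per-condition estimates (mean, scatter, p, significance)."""
    rows = []
    for condition in ct.conditions():
        if condition == reference_condition:
            ref = None
        else:
            ref = reference_condition
        for gene in ct.genes():
            est = estimate_enrichment(ct, gene, condition, efficiency, ref)
            lo, hi = est.scatter
            rows.append(
                {
                    "gene_id": gene,
                    "condition": condition,
                    "n_replicates": est.replicate_values.size,
                    "mean_fold_enrichment": est.mean,
                    "scatter_min": lo,
                    "scatter_max": hi,
                    "p_value": est.p_value,
                    "significant": est.significant,
                }
            )
    return pd.DataFrame(rows)


def condition_ratio(treated: EnrichmentEstimate, untreated: EnrichmentEstimate) -> float:
    """Mean-occupancy ratio between conditions; 1.0 means no change."""
    if treated.gene_id != untreated.gene_id:
        raise QuantifyError(
            f"gene mismatch: {treated.gene_id!r} vs {untreated.gene_id!r}"
        )
    if untreated.mean <= 0:
        raise QuantifyError("untreated mean must be > 0")
    return treated.mean / untreated.mean


def replicate_ttest(values_a, values_b) -> float:
    """Two-tailed pooled-variance Student p for two replicate sets."""
    return pooled_ttest(values_a, values_b).p_value


def band_ratio(target_intensity: float, control_intensity: float) -> float:
    """Blot band level normalized to a loading control (e.g. U4 RNA, H3)."""
    if control_intensity <= 0:
        raise QuantifyError("control intensity must be > 0")
    return target_intensity / control_intensity


@dataclass
class NormalizedAbundance:
    """Library-size-normalized counts with log2 values and fold changes."""

    normalized: pd.DataFrame
    log2_values: pd.DataFrame
    pseudocount: float

    def fold_change(self, numerator: str, denominator: str) -> pd.Series:
        """Per-row ratio of normalized values between two samples."""
        for s in (numerator, denominator):
            if s not in self.normalized.columns:
                raise QuantifyError(f"unknown sample {s!r}")
        denom = self.normalized[denominator]
        if (denom <= 0).any():
            logger.info("fold_change: zero denominators produce inf")
        return self.normalized[numerator] / denom

    def log2_fold_change(self, numerator: str, denominator: str) -> pd.Series:
        return self.log2_values[numerator] - self.log2_values[denominator]


def normalize_counts(
    counts: CountTable,
    method: str = "per_million",
    pseudocount: float = 1.0,
) -> NormalizedAbundance:
    """Counts-per-million normalization with log2(value + pseudocount).

    A stand-in for hybridization-sequencing count normalization:
    per-column library-size scaling to counts per million, then log2 with
    a pseudocount; within-sample rank order of counts is preserved.
    """
    if method != "per_million":
        raise QuantifyError(f"unknown normalization method {method!r}")
    counts.require_positive_totals()
    df = counts.counts.astype(float)
    normalized = df / df.sum(axis=0) * 1e6
    log2_values = np.log2(normalized + pseudocount)
    return NormalizedAbundance(normalized, log2_values, pseudocount)
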