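"""Pairwise ddCt relative copy numbers.

For a tumour/control pair and an ordered gene pair (g, h) the relative copy
number of g normalized to h is

    dCt_tumour  = Ct(g, tumour)  - Ct(h, tumour)
    dCt_control = Ct(g, control) - Ct(h, control)
    ddCt        = dCt_tumour - dCt_control
    R(g, h)     = E ** (-ddCt)          (E = amplification efficiency, 2.0)

Within-sample template-dose offsets cancel in each dCt, so R is invariant
to how much DNA was loaded per sample.  Replicates are collapsed to an
arithmetic mean Ct before pairing; each gene is then summarized by the mean
and standard deviation of its ratios against every other usable panel gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .panel_io import CallingConfig, CtTable, Panel, SamplePair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseRatio:
    """Relative copy number of one ordered gene pair in one tumour/control pair."""

    patient_id: str
    gene_numerator: str
    gene_denominator: str
    delta_delta_ct: float
    ratio: float


@dataclass(frozen=True)
class GeneRelativeCN:
    """Per-gene summary of pairwise ratios against all panel partners."""

    patient_id: str
    gene: str
    mean_ratio: float
    sd_ratio: float
    n_partners: int


def mean_ct(
    ct: CtTable, sample_id: str, assay: str, max_ct: float | None = None
) -> float:
    """Arithmetic mean of the non-missing replicate Ct values.

    Raises
    ------
    MissingDataError
        If every replicate is missing (or censored by ``max_ct``).
    """
    cts = ct.replicate_cts(sample_id, assay).dropna()
    if max_ct is not None:
        cts = cts[cts <= max_ct]
    if len(cts) == 0:
        raise MissingDataError(
            f"no usable Ct replicate for sample {sample_id!r}, assay {assay!r}"
        )
    return float(cts.mean())


def pairwise_ratio(
    ct: CtTable,
    pair: SamplePair,
    g: str,
    h: str,
    config: CallingConfig = CallingConfig(),
) -> PairwiseRatio:
    """ddCt relative copy number of assay ``g`` normalized to assay ``h``."""
    if g == h:
        return PairwiseRatio(pair.patient_id, g, h, 0.0, 1.0)
    ct_g_t = mean_ct(ct, pair.tumour_sample_id, g, config.max_ct)
    ct_h_t = mean_ct(ct, pair.tumour_sample_id, h, config.max_ct)
    ct_g_c = mean_ct(ct, pair.control_sample_id, g, config.max_ct)
    ct_h_c = mean_ct(ct, pair.control_sample_id, h, config.max_ct)
    ddct = (ct_g_t - ct_h_t) - (ct_g_c - ct_h_c)
    return PairwiseRatio(
        pair.patient_id, g, h, ddct, float(config.efficiency ** (-ddct))
    )


def usable_assays(
    ct: CtTable,
    pair: SamplePair,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> list[str]:
    """Panel assays with at least one usable Ct in both samples of the pair.

    Assays with no amplification in either sample are dropped from the
    pair's panel with a logged warning; the score denominator shrinks
    accordingly.
    """
    usable, dropped = [], []
    for name in panel.names:
        if ct.has_signal(pair.tumour_sample_id, name, config.max_ct) and ct.has_signal(
            pair.control_sample_id, name, config.max_ct
        ):
            usable.append(name)
        else:
            dropped.append(name)
    if dropped:
        logger.warning(
            "pair %s: assays %s have no usable Ct in tumour or control and "
            "are excluded from the pairwise panel",
            pair.patient_id,
            dropped,
        )
    return usable


def pair_ratio_table(
    ct: CtTable,
    pair: SamplePair,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> pd.DataFrame:
    """All ordered pairwise ratios (g != h) over the pair's usable assays.

    Returns a DataFrame with columns ``patient_id, gene_numerator,
    gene_denominator, delta_delta_ct, ratio``.
    """
    assays = usable_assays(ct, pair, panel, config)
    if not assays:
        raise MissingDataError(
            f"pair {pair.patient_id!r}: no assay has usable Ct in both samples"
        )
    means = {
        (s, a): mean_ct(ct, s, a, config.max_ct)
        for s in (pair.tumour_sample_id, pair.control_sample_id)
        for a in assays
    }
    rows = []
    for g in assays:
        for h in assays:
            if g == h:
                continue
            ddct = (
                means[(pair.tumour_sample_id, g)] - means[(pair.tumour_sample_id, h)]
            ) - (
                means[(pair.control_sample_id, g)]
                - means[(pair.control_sample_id, h)]
            )
            rows.append(
                {
                    "patient_id": pair.patient_id,
                    "gene_numerator": g,
                    "gene_denominator": h,
                    "delta_delta_ct": ddct,
                    "ratio": float(config.efficiency ** (-ddct)),
                }
            )
    return pd.DataFrame(rows)


def gene_relative_cn(ratio_table: pd.DataFrame, gene: str) -> GeneRelativeCN:
    """Mean and sample SD of a gene's ratios over all panel partners."""
    rows = ratio_table[ratio_table["gene_numerator"] == gene]
    if len(rows) == 0:
        raise MissingDataError(f"no pairwise ratios with {gene!r} as numerator")
    ratios = rows["ratio"].to_numpy()
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return GeneRelativeCN(
        patient_id=str(rows["patient_id"].iloc[0]),
        gene=gene,
        mean_ratio=float(ratios.mean()),
        sd_ratio=sd,
        n_partners=len(ratios),
    )


def relative_cn_table(ratio_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary table (one row per numerator gene)."""
    rows = []
    for gene in ratio_table["gene_numerator"].unique():
        cn = gene_relative_cn(ratio_table, gene)
        rows.append(
            {
                "patient_id": cn.patient_id,
                "gene": cn.gene,
                "mean_ratio": cn.mean_ratio,
                "sd_ratio": cn.sd_ratio,
                "n_partners": cn.n_partners,
            }
        )
    return pd.DataFrame(rows)
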