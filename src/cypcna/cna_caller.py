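"""Scoring, alteration calling, reference validation and absolute copy number.

Each pairwise relative copy number is scored against an equivalence band:
0 inside [0.8, 1.25], -1 below, +1 above.  Summing a gene's scores over its
panel partners gives an integer in [-(p-1), +(p-1)] for a p-gene panel; a
sum <= -5 calls a deletion and >= +5 a multiplication (defaults for the
10-gene panel).  Candidate reference genes that receive no call are treated
as validated two-copy references; the absolute copy number of any gene is
then the control ploidy (2) times the mean of its ratios against the
validated references.

Under a single-copy-event mixture model a population-average copy number
between 1 and 3 is interpreted as the fraction of tumour cells carrying a
one-copy loss (2 - CN) or gain (CN - 2): e.g. CN = 1.6 means 40% of cells
lost one copy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .ddct_engine import pair_ratio_table, relative_cn_table
from .errors import CypCnaError, MissingDataError, TooFewReferencesError
from .panel_io import ROLE_REFERENCE, CallingConfig, CtTable, Panel, SamplePair

logger = logging.getLogger(__name__)

DELETION = "deletion"
MULTIPLICATION = "multiplication"
NO_CALL = "none"

LOSS = "loss"
GAIN = "gain"
NO_EVENT = "none"


@dataclass(frozen=True)
class GeneScoreCard:
    """Per-gene score sum and alteration call for one tumour/control pair."""

    patient_id: str
    gene: str
    score_sum: int
    call: str
    per_partner_scores: dict | None = None

    def __post_init__(self):
        if self.per_partner_scores is not None:
            total = sum(self.per_partner_scores.values())
            if total != self.score_sum:
                raise CypCnaError(
                    f"{self.gene}: score_sum {self.score_sum} != sum of "
                    f"per-partner scores {total}"
                )


@dataclass(frozen=True)
class AbsoluteCN:
    """Reference-validated absolute copy number with mixture interpretation."""

    patient_id: str
    gene: str
    copy_number: float
    n_references_used: int
    reference_genes: tuple
    tumour_fraction: float | None
    event_direction: str


def score_ratio(ratio: float, config: CallingConfig = CallingConfig()) -> int:
    """Score one pairwise relative copy number against the acceptance band.

    0 inside the closed band [lower_bound, upper_bound], -1 below, +1 above.
    """
    if not ratio > 0:
        raise CypCnaError(f"relative copy number must be positive, got {ratio}")
    if ratio < config.lower_bound:
        return -1
    if ratio > config.upper_bound:
        return +1
    return 0


def call_from_score_sum(score_sum: int, score_threshold: int) -> str:
    """Map a per-gene score sum to deletion / none / multiplication."""
    if score_sum <= -score_threshold:
        return DELETION
    if score_sum >= score_threshold:
        return MULTIPLICATION
    return NO_CALL


def score_gene(
    patient_id: str,
    gene: str,
    partner_ratios: dict,
    config: CallingConfig = CallingConfig(),
) -> GeneScoreCard:
    """Score one gene against all of its panel partners.

    ``partner_ratios`` maps partner assay name -> R(gene, partner).
    """
    if not partner_ratios:
        raise MissingDataError(f"{gene}: no partner ratios to score")
    scores = {h: score_ratio(r, config) for h, r in partner_ratios.items()}
    total = sum(scores.values())
    return GeneScoreCard(
        patient_id=patient_id,
        gene=gene,
        score_sum=total,
        call=call_from_score_sum(total, config.score_threshold),
        per_partner_scores=scores,
    )


def score_pair(
    ratio_table: pd.DataFrame,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> dict[str, GeneScoreCard]:
    """Score every assay in a pair's ratio table.

    Partners are restricted to assays of *other* genes, so allele-specific
    assays of the same gene are never scored against each other.
    """
    assays = list(ratio_table["gene_numerator"].unique())
    cards = {}
    for name in assays:
        gene = panel.get(name).gene
        rows = ratio_table[ratio_table["gene_numerator"] == name]
        partner_ratios = {
            r.gene_denominator: r.ratio
            for r in rows.itertuples()
            if panel.get(r.gene_denominator).gene != gene
        }
        cards[name] = score_gene(
            str(rows["patient_id"].iloc[0]), name, partner_ratios, config
        )
    return cards


def select_references(
    scorecards: dict[str, GeneScoreCard],
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> list[str]:
    """Reference-candidate genes whose copy number is validated unchanged.

    A candidate survives when its alteration call is ``none``; target CYP
    assays are never returned.  Selection is single-pass: genes are scored
    once against the full panel, then the flagged ones are dropped.

    Raises
    ------
    TooFewReferencesError
        If fewer than ``config.min_reference_genes`` candidates survive.
    """
    survivors = [
        a.name
        for a in panel.assays
        if a.role == ROLE_REFERENCE
        and a.name in scorecards
        and scorecards[a.name].call == NO_CALL
    ]
    if len(survivors) < config.min_reference_genes:
        raise TooFewReferencesError(survivors, config.min_reference_genes)
    return survivors


def absolute_from_mean_ratio(
    mean_ratio: float, config: CallingConfig = CallingConfig()
) -> float:
    """Absolute copies per cell from a validated-reference mean relative CN.

    The control tissue is assumed diploid, so the relative copy number is
    multiplied by the control ploidy (2 by default).
    """
    if not mean_ratio > 0:
        raise CypCnaError(f"mean relative copy number must be positive, got {mean_ratio}")
    return config.ploidy_of_control * mean_ratio


def tumour_fraction(
    copy_number: float, config: CallingConfig = CallingConfig()
) -> tuple[str, float | None]:
    """Interpret an absolute copy number under the single-copy-event model.

    Returns ``(event_direction, fraction)`` where the fraction of tumour
    cells carrying a one-copy loss (or gain) is |ploidy - CN|.  Within the
    no-call band around the control ploidy the event is ``none`` with
    fraction 0; outside the model's domain [1, 3] the fraction is omitted
    (``None``) because more than one copy per cell must have changed.
    """
    delta = copy_number - config.ploidy_of_control
    if abs(delta) < config.no_call_band:
        return NO_EVENT, 0.0
    direction = GAIN if delta > 0 else LOSS
    if 1.0 <= copy_number <= 3.0:
        return direction, abs(delta)
    return direction, None


def absolute_cn(
    ratio_table: pd.DataFrame,
    assay_name: str,
    references: list[str],
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> AbsoluteCN:
    """Absolute copy number of one assay from validated references.

    The gene's ratios against every validated reference of a *different*
    gene are averaged and multiplied by the control ploidy; a reference
    gene therefore never normalizes itself.
    """
    gene = panel.get(assay_name).gene
    refs_used = tuple(r for r in references if panel.get(r).gene != gene)
    if not refs_used:
        raise TooFewReferencesError([], 1)
    rows = ratio_table[
        (ratio_table["gene_numerator"] == assay_name)
        & (ratio_table["gene_denominator"].isin(refs_used))
    ]
    if len(rows) != len(refs_used):
        raise MissingDataError(
            f"{assay_name}: ratios against references {refs_used} incomplete"
        )
    cn = absolute_from_mean_ratio(float(rows["ratio"].mean()), config)
    direction, fraction = tumour_fraction(cn, config)
    return AbsoluteCN(
        patient_id=str(rows["patient_id"].iloc[0]),
        gene=assay_name,
        copy_number=cn,
        n_references_used=len(refs_used),
        reference_genes=refs_used,
        tumour_fraction=fraction,
        event_direction=direction,
    )


@dataclass
class PairCallResult:
    """Full calling output for one tumour/control pair."""

    patient_id: str
    table: pd.DataFrame
    references: list[str]
    scorecards: dict[str, GeneScoreCard] = field(repr=False, default_factory=dict)
    ratio_table: pd.DataFrame | None = field(repr=False, default=None)


def call_pair(
    ct: CtTable,
    pair: SamplePair,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> PairCallResult:
    """Run the full calling pipeline on one tumour/control pair.

    Computes all pairwise ratios, scores every assay, validates the
    reference set, and derives absolute copy numbers and tumour fractions
    for every assay.
    """
    panel.require_callable()
    ratios = pair_ratio_table(ct, pair, panel, config)
    n_usable = ratios["gene_numerator"].nunique()
    if n_usable < len(panel):
        warnings.warn(
            f"pair {pair.patient_id}: only {n_usable} of {len(panel)} assays "
            f"usable; score_threshold={config.score_threshold} was chosen for "
            "a 10-gene panel and may need rescaling",
            stacklevel=2,
        )
    cards = score_pair(ratios, panel, config)
    references = select_references(cards, panel, config)
    summary = relative_cn_table(ratios)

    rows = []
    for name in summary["gene"]:
        card = cards[name]
        abs_cn = absolute_cn(ratios, name, references, panel, config)
        rel = summary[summary["gene"] == name].iloc[0]
        rows.append(
            {
                "patient_id": pair.patient_id,
                "gene": name,
                "mean_ratio": rel["mean_ratio"],
                "sd_ratio": rel["sd_ratio"],
                "n_partners": int(rel["n_partners"]),
                "score_sum": card.score_sum,
                "call": card.call,
                "copy_number": abs_cn.copy_number,
                "n_references_used": abs_cn.n_references_used,
                "tumour_fraction": abs_cn.tumour_fraction,
                "event_direction": abs_cn.event_direction,
            }
        )
    return PairCallResult(
        patient_id=pair.patient_id,
        table=pd.DataFrame(rows),
        references=references,
        scorecards=cards,
        ratio_table=ratios,
    )


def call_cohort(
    ct: CtTable,
    pairs,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Call every pair; returns the concatenated table and per-pair references."""
    tables, refs = [], {}
    for pair in pairs:
        result = call_pair(ct, pair, panel, config)
        tables.append(result.table)
        refs[pair.patient_id] = result.references
    return pd.concat(tables, ignore_index=True), refs
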