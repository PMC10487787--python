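"""Star-allele frequency tabulation and functional-gain classification.

Allele and genotype frequencies summarize the cohort's germline
pharmacogenetics; a tumour is classified as carrying a *functional* CYP
multiplication only when the extra copies are expected to increase
paclitaxel-metabolizing capacity:

* CYP2C8 — multiplication of the reduced-activity CYP2C8*3 allele does not
  raise activity, so in *1/*3 heterozygotes the multiplication must be
  attributable to the allele-discriminating *1 assay; in *1/*1 patients any
  CYP2C8 multiplication counts.
* CYP3A4 — both *1 and *1B produce functional enzyme, so any CYP3A4
  multiplication counts regardless of genotype.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cna_caller import MULTIPLICATION
from .errors import DuplicateRecordError, MissingDataError
from .panel_io import GenotypeRecord

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"\*(\d+)([A-Z]*)")


def _allele_sort_key(allele: str):
    m = _ALLELE_RE.fullmatch(allele)
    if m is None:
        return (float("inf"), allele)
    return (int(m.group(1)), m.group(2))


def genotype_label(allele1: str, allele2: str) -> str:
    """Canonical unordered diplotype label, e.g. ``"*1/*3"``."""
    a, b = sorted((allele1, allele2), key=_allele_sort_key)
    return f"{a}/{b}"


def round_percent(count: int, total: int) -> float:
    """Relative frequency in percent, reported to one decimal place.

    The percentage is carried at two decimals and then reduced to one, with
    halves rounded up at each stage (spreadsheet-style display rounding).
    """
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    pct = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(pct)


@dataclass
class FrequencyTable:
    """Allele and genotype counts and percent frequencies for one gene."""

    gene: str
    n_patients: int
    allele_counts: dict = field(default_factory=dict)
    allele_freq_percent: dict = field(default_factory=dict)
    genotype_counts: dict = field(default_factory=dict)
    genotype_freq_percent: dict = field(default_factory=dict)


def allele_frequencies(genotypes, gene: str) -> FrequencyTable:
    """Tabulate star-allele and diplotype frequencies for one gene.

    Each of a patient's two alleles contributes one count, so allele counts
    sum to 2N and genotype counts to N.

    Raises
    ------
    DuplicateRecordError
        If a patient has more than one record for the gene.
    """
    records = [g for g in genotypes if g.gene == gene]
    patients = [g.patient_id for g in records]
    dups = {p for p in patients if patients.count(p) > 1}
    if dups:
        raise DuplicateRecordError(
            f"patients with duplicate {gene} genotype records: {sorted(dups)}"
        )

    table = FrequencyTable(gene=gene, n_patients=len(records))
    for rec in records:
        for allele in rec.alleles:
            table.allele_counts[allele] = table.allele_counts.get(allele, 0) + 1
        label = genotype_label(*rec.alleles)
        table.genotype_counts[label] = table.genotype_counts.get(label, 0) + 1

    n_alleles = 2 * len(records)
    table.allele_counts = dict(
        sorted(table.allele_counts.items(), key=lambda kv: _allele_sort_key(kv[0]))
    )
    table.genotype_counts = dict(sorted(table.genotype_counts.items()))
    table.allele_freq_percent = {
        a: round_percent(c, n_alleles) for a, c in table.allele_counts.items()
    }
    table.genotype_freq_percent = {
        g: round_percent(c, len(records)) for g, c in table.genotype_counts.items()
    }
    return table


@dataclass(frozen=True)
class FunctionalGainCall:
    """Whether a tumour carries a multiplication expected to raise
    paclitaxel-metabolizing capacity."""

    patient_id: str
    cyp2c8_functional_multiplication: bool
    cyp3a4_multiplication: bool

    @property
    def any_functional_gain(self) -> bool:
        return self.cyp2c8_functional_multiplication or self.cyp3a4_multiplication


def _functional_allele_labels(record: GenotypeRecord | None) -> set[str]:
    if record is None:
        return {"*1"}
    return {a for a in record.alleles}


def functional_gain(
    patient_id: str,
    calls: dict[str, str],
    genotypes,
) -> FunctionalGainCall:
    """Classify a tumour for functional CYP2C8/CYP3A4 multiplication.

    Parameters
    ----------
    patient_id
        Patient whose tumour was called.
    calls
        Mapping of assay name (``"CYP2C8"``, ``"CYP2C8*1"``, ``"CYP3A4"``,
        ...) to alteration call for this patient's tumour.
    genotypes
        The patient's germline :class:`GenotypeRecord` list (any genes).

    Raises
    ------
    MissingDataError
        If no CNA call exists for CYP2C8 or CYP3A4.
    """
    geno = {g.gene: g for g in genotypes if g.patient_id == patient_id}

    c8_calls = {a: c for a, c in calls.items() if a.startswith("CYP2C8")}
    a4_calls = {a: c for a, c in calls.items() if a.startswith("CYP3A4")}
    if not c8_calls or not a4_calls:
        raise MissingDataError(
            f"patient {patient_id}: CNA calls required for both CYP2C8 and "
            f"CYP3A4 (got {sorted(calls)})"
        )

    c8_geno = geno.get("CYP2C8")
    c8_alleles = set(c8_geno.alleles) if c8_geno is not None else {"*1"}
    if c8_alleles == {"*1"}:
        # Homozygous wild-type: every CYP2C8 copy is functional.
        c8_gain = any(c == MULTIPLICATION for c in c8_calls.values())
    elif "*1" in c8_alleles:
        # Heterozygote: the gain must sit on the functional *1 allele, so
        # only the allele-discriminating *1 assay can establish it.
        if "CYP2C8*1" in c8_calls:
            c8_gain = c8_calls["CYP2C8*1"] == MULTIPLICATION
            if not c8_gain and any(c == MULTIPLICATION for c in c8_calls.values()):
                logger.warning(
                    "patient %s: CYP2C8 multiplication detected but not "
                    "attributable to the *1 assay; not counted as functional",
                    patient_id,
                )
        else:
            c8_gain = False
            if any(c == MULTIPLICATION for c in c8_calls.values()):
                logger.warning(
                    "patient %s: *1/%s heterozygote with total CYP2C8 "
                    "multiplication but no allele-discriminating *1 assay; "
                    "functional gain left false",
                    patient_id,
                    (c8_alleles - {"*1"}).pop(),
                )
    else:
        # No functional allele to multiply.
        c8_gain = False

    # CYP3A4: *1 and *1B are both functional, so allele identity is moot.
    a4_gain = any(c == MULTIPLICATION for c in a4_calls.values())

    return FunctionalGainCall(
        patient_id=patient_id,
        cyp2c8_functional_multiplication=c8_gain,
        cyp3a4_multiplication=a4_gain,
    )


def gain_response_contingency(gain_calls, responses) -> np.ndarray:
    """2x2 table (rows: non-responder, responder; cols: gain, no gain)."""
    from .panel_io import NON_RESPONDER, RESPONDER

    status = {r.patient_id: r.status for r in responses}
    table = np.zeros((2, 2), dtype=int)
    for call in gain_calls:
        if call.patient_id not in status:
            logger.warning("no response label for patient %s; skipped", call.patient_id)
            continue
        row = 0 if status[call.patient_id] == NON_RESPONDER else 1
        col = 0 if call.any_functional_gain else 1
        table[row, col] += 1
    return table
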