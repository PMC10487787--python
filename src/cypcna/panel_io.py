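"""Data model, readers and validation for qPCR copy-number panels.

The calling pipeline works on four kinds of input:

* a long-format **Ct table** with one row per (sample, assay, replicate)
  threshold-cycle measurement,
* a **panel manifest** naming each assay, its gene, its role (``target`` CYP
  vs ``reference_candidate``) and an optional allele label for
  allele-discriminating assays,
* a **sample-pair manifest** matching each tumour sample to its control
  (blood or non-tumourous lung tissue),
* optional **genotype** and **clinical response** tables for the
  pharmacogenetic association analysis.

Long-format delimited text (CSV or TSV) is the canonical Ct input; exports
from microfluidic qPCR instruments vary, and a flat
``sample_id, gene, allele_label, replicate, ct`` contract is the simplest
stable one.  Missing Ct values ("no amplification", written as an empty
field or ``NA``) are retained as missing measurements and never imputed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DuplicateRecordError, SchemaError

logger = logging.getLogger(__name__)

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference_candidate"
CONTROL_KINDS = ("blood", "normal_lung")
RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: Required columns of a long-format Ct table (allele_label may be omitted).
CT_COLUMNS = ("sample_id", "gene", "allele_label", "replicate", "ct")

#: Star-allele vocabulary for the genotyped paclitaxel-metabolizing CYPs.
DEFAULT_ALLELE_VOCABULARY: dict[str, frozenset[str]] = {
    "CYP2C8": frozenset({"*1", "*3", "*4"}),
    "CYP3A4": frozenset({"*1", "*1B", "*22"}),
    "CYP3A5": frozenset({"*1", "*3"}),
}


@dataclass(frozen=True)
class Assay:
    """One qPCR copy-number assay.

    Parameters
    ----------
    gene
        HGNC gene symbol, e.g. ``"CYP2C8"``.
    role
        ``"target"`` for the drug-metabolizing CYPs whose copy number is the
        question, ``"reference_candidate"`` for genes expected diploid that
        compete to become normalization references.
    allele_label
        Optional star-allele tag (``"*1"``, ``"*3"``) for assays whose
        primers discriminate a specific allele of the gene.
    chromosome_location
        Free-text cytogenetic band annotation, e.g. ``"10q23.33"``.
    """

    gene: str
    role: str = ROLE_REFERENCE
    allele_label: str | None = None
    chromosome_location: str | None = None

    def __post_init__(self):
        if self.role not in (ROLE_TARGET, ROLE_REFERENCE):
            raise SchemaError(
                f"assay {self.gene!r}: role must be one of "
                f"{(ROLE_TARGET, ROLE_REFERENCE)}, got {self.role!r}"
            )
        if not self.gene:
            raise SchemaError("assay gene symbol must be non-empty")

    @property
    def name(self) -> str:
        """Unique assay identifier: gene symbol plus allele tag if any."""
        return self.gene + (self.allele_label or "")


class Panel:
    """An ordered collection of assays with unique (gene, allele) identity."""

    def __init__(self, assays):
        self.assays: tuple[Assay, ...] = tuple(assays)
        names = [a.name for a in self.assays]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise DuplicateRecordError(f"duplicate assays in panel: {sorted(dups)}")
        self._by_name = {a.name: a for a in self.assays}

    def __iter__(self):
        return iter(self.assays)

    def __len__(self):
        return len(self.assays)

    def __contains__(self, name):
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.assays]

    @property
    def genes(self) -> list[str]:
        seen = []
        for a in self.assays:
            if a.gene not in seen:
                seen.append(a.gene)
        return seen

    def get(self, name: str) -> Assay:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"assay {name!r} is not in the panel") from None

    @property
    def targets(self) -> list[Assay]:
        return [a for a in self.assays if a.role == ROLE_TARGET]

    @property
    def reference_candidates(self) -> list[Assay]:
        return [a for a in self.assays if a.role == ROLE_REFERENCE]

    def require_callable(self):
        """A calling run needs at least two reference candidates."""
        if len(self.reference_candidates) < 2:
            raise SchemaError(
                "panel must contain at least 2 reference_candidate assays "
                f"(found {len(self.reference_candidates)})"
            )

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "assays" not in doc:
            raise SchemaError(f"panel manifest {path} must contain an 'assays' list")
        assays = []
        for entry in doc["assays"]:
            assays.append(
                Assay(
                    gene=entry["gene"],
                    role=entry.get("role", ROLE_REFERENCE),
                    allele_label=entry.get("allele_label") or None,
                    chromosome_location=entry.get("chromosome_location"),
                )
            )
        return cls(assays)

    def to_yaml(self, path):
        doc = {
            "assays": [
                {
                    "gene": a.gene,
                    "role": a.role,
                    "allele_label": a.allele_label,
                    "chromosome_location": a.chromosome_location,
                }
                for a in self.assays
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_panel() -> Panel:
    """The standard 10-assay panel: CYP2C8 and CYP3A4 targets plus eight
    candidate reference genes spread over different chromosomes."""
    return Panel(
        [
            Assay("RPPH1", ROLE_REFERENCE, chromosome_location="14q11.2"),
            Assay("ALB", ROLE_REFERENCE, chromosome_location="4q13.3"),
            Assay("B2M", ROLE_REFERENCE, chromosome_location="15q21.1"),
            Assay("BCKDHA", ROLE_REFERENCE, chromosome_location="19q13.2"),
            Assay("CD36", ROLE_REFERENCE, chromosome_location="7q21.11"),
            Assay("F5", ROLE_REFERENCE, chromosome_location="1q24.2"),
            Assay("MPO", ROLE_REFERENCE, chromosome_location="17q22"),
            Assay("TBP", ROLE_REFERENCE, chromosome_location="6q27"),
            Assay("CYP3A4", ROLE_TARGET, chromosome_location="7q22.1"),
            Assay("CYP2C8", ROLE_TARGET, chromosome_location="10q23.33"),
        ]
    )


@dataclass(frozen=True)
class SamplePair:
    """A tumour sample matched to its normalization control."""

    patient_id: str
    tumour_sample_id: str
    control_sample_id: str
    control_kind: str = "blood"

    def __post_init__(self):
        if self.tumour_sample_id == self.control_sample_id:
            raise SchemaError(
                f"pair {self.patient_id!r}: tumour and control sample ids "
                "must differ"
            )
        if self.control_kind not in CONTROL_KINDS:
            raise SchemaError(
                f"pair {self.patient_id!r}: control_kind must be one of "
                f"{CONTROL_KINDS}, got {self.control_kind!r}"
            )


def read_sample_pairs(path) -> list[SamplePair]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pairs" not in doc:
        raise SchemaError(f"pair manifest {path} must contain a 'pairs' list")
    return [
        SamplePair(
            patient_id=str(e["patient_id"]),
            tumour_sample_id=str(e["tumour_sample_id"]),
            control_sample_id=str(e["control_sample_id"]),
            control_kind=e.get("control_kind", "blood"),
        )
        for e in doc["pairs"]
    ]


def write_sample_pairs(pairs, path):
    doc = {
        "pairs": [
            {
                "patient_id": p.patient_id,
                "tumour_sample_id": p.tumour_sample_id,
                "control_sample_id": p.control_sample_id,
                "control_kind": p.control_kind,
            }
            for p in pairs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class GenotypeRecord:
    """Germline star-allele diplotype of one patient for one CYP gene."""

    patient_id: str
    gene: str
    allele1: str
    allele2: str

    def __post_init__(self):
        vocab = DEFAULT_ALLELE_VOCABULARY.get(self.gene)
        if vocab is not None:
            for allele in (self.allele1, self.allele2):
                if allele not in vocab:
                    raise SchemaError(
                        f"genotype {self.patient_id}/{self.gene}: allele "
                        f"{allele!r} not in vocabulary {sorted(vocab)}"
                    )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)


def read_genotypes(path) -> list[GenotypeRecord]:
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "gene", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"genotype table {path} must have columns {sorted(required)}"
        )
    records = [
        GenotypeRecord(r.patient_id, r.gene, r.allele1, r.allele2)
        for r in df.itertuples()
    ]
    keys = [(g.patient_id, g.gene) for g in records]
    dups = {k for k in keys if keys.count(k) > 1}
    if dups:
        raise DuplicateRecordError(
            f"duplicate (patient, gene) genotype records: {sorted(dups)}"
        )
    return records


@dataclass(frozen=True)
class ResponseLabel:
    """RECIST-derived therapy outcome, consumed as a binary label."""

    patient_id: str
    status: str

    def __post_init__(self):
        if self.status not in (RESPONDER, NON_RESPONDER):
            raise SchemaError(
                f"response for {self.patient_id!r}: status must be "
                f"'{RESPONDER}' or '{NON_RESPONDER}', got {self.status!r}"
            )


def read_responses(path) -> list[ResponseLabel]:
    df = pd.read_csv(path, dtype=str)
    if not {"patient_id", "status"}.issubset(df.columns):
        raise SchemaError(
            f"response table {path} must have columns patient_id, status"
        )
    labels = [ResponseLabel(r.patient_id, r.status) for r in df.itertuples()]
    ids = [l.patient_id for l in labels]
    dups = {i for i in ids if ids.count(i) > 1}
    if dups:
        raise DuplicateRecordError(f"duplicate response labels: {sorted(dups)}")
    return labels


@dataclass(frozen=True)
class CallingConfig:
    """Tunable thresholds of the scoring and absolute-quantification rules.

    Attributes
    ----------
    lower_bound, upper_bound
        Equivalence band on a pairwise relative copy number; ratios inside
        ``[lower_bound, upper_bound]`` (inclusive) score 0.  Defaults
        0.8 / 1.25; keeping ``upper_bound == 1/lower_bound`` preserves the
        antisymmetry of pairwise scores.
    score_threshold
        Minimum absolute score sum that flags a deletion (``<= -threshold``)
        or a multiplication (``>= +threshold``).  Default 5, chosen for a
        10-gene panel (9 comparisons per gene).
    min_reference_genes
        Minimum number of validated reference genes required before absolute
        quantification is attempted.
    ploidy_of_control
        Copies of every gene assumed in the control tissue (2 for normal
        diploid blood or lung).
    efficiency
        Amplification efficiency E in R = E**(-ddCt); 2.0 means perfect
        doubling per cycle.
    max_ct
        Optional censoring threshold: replicate Ct values above it are
        treated as missing.  ``None`` disables censoring.
    no_call_band
        Half-width of the absolute-copy-number band around the control
        ploidy inside which no tumour-fraction event is reported.
    """

    lower_bound: float = 0.8
    upper_bound: float = 1.25
    score_threshold: int = 5
    min_reference_genes: int = 3
    ploidy_of_control: float = 2.0
    efficiency: float = 2.0
    max_ct: float | None = None
    no_call_band: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.lower_bound < 1.0 < self.upper_bound):
            raise SchemaError(
                "acceptance band must satisfy 0 < lower < 1 < upper; got "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        if self.score_threshold < 1:
            raise SchemaError("score_threshold must be >= 1")
        if self.efficiency <= 1.0:
            raise SchemaError("amplification efficiency must exceed 1")
        if abs(self.upper_bound * self.lower_bound - 1.0) > 1e-9:
            warnings.warn(
                "upper_bound != 1/lower_bound: pairwise score antisymmetry "
                "is broken and per-gene score sums will not cancel",
                stacklevel=2,
            )


class CtTable:
    """Validated long-format table of replicate Ct measurements.

    Wraps a :class:`pandas.DataFrame` with columns
    ``sample_id, gene, allele_label, replicate, ct, assay`` where ``assay``
    is the derived unique assay name and ``ct`` is float (NaN = no
    amplification).
    """

    def __init__(self, data: pd.DataFrame, panel: Panel):
        df = data.copy()
        missing_cols = {"sample_id", "gene", "replicate", "ct"} - set(df.columns)
        if missing_cols:
            raise SchemaError(f"Ct table missing columns {sorted(missing_cols)}")
        if "allele_label" not in df.columns:
            df["allele_label"] = ""
        df["sample_id"] = df["sample_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["allele_label"] = df["allele_label"].fillna("").astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce").astype(float)
        df["assay"] = df["gene"] + df["allele_label"]

        for idx, row in df.iterrows():
            if row["assay"] not in panel:
                raise SchemaError(
                    f"row {idx}: assay {row['assay']!r} (gene {row['gene']!r}) "
                    "is not defined in the panel"
                )
            ct = row["ct"]
            if not math.isnan(ct) and (not math.isfinite(ct) or ct <= 0):
                raise SchemaError(
                    f"row {idx}: ct must be finite and > 0 cycles, got {ct}"
                )
        if (df["replicate"] < 1).any():
            raise SchemaError("replicate indices must be positive integers")

        key = df[["sample_id", "assay", "replicate"]]
        dup = key.duplicated()
        if dup.any():
            first = df[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicate measurement for (sample, assay, replicate) = "
                f"({first['sample_id']}, {first['assay']}, {first['replicate']})"
            )

        self.data = df.reset_index(drop=True)
        self.panel = panel

    def __len__(self):
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def replicate_cts(self, sample_id: str, assay: str) -> pd.Series:
        """All replicate Ct values (possibly NaN) for one sample and assay."""
        mask = (self.data["sample_id"] == sample_id) & (self.data["assay"] == assay)
        return self.data.loc[mask, "ct"]

    def has_signal(self, sample_id: str, assay: str, max_ct: float | None = None) -> bool:
        """True if at least one usable (non-missing, uncensored) replicate exists."""
        cts = self.replicate_cts(sample_id, assay).dropna()
        if max_ct is not None:
            cts = cts[cts <= max_ct]
        return len(cts) > 0


def read_ct_table(path, panel: Panel, sep: str | None = None) -> CtTable:
    """Read a long-format delimited Ct table.

    The delimiter is inferred from the extension (``.tsv`` = tab, otherwise
    comma) unless ``sep`` is given.  Empty or ``NA`` ct fields become
    missing measurements.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "gene": str})
    return CtTable(df, panel)


def write_ct_table(table: CtTable, path, sep: str | None = None):
    """Write a Ct table back to delimited text (inverse of read_ct_table)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out = table.data[["sample_id", "gene", "allele_label", "replicate", "ct"]]
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


@dataclass
class ValidationReport:
    """Report of per-pair, per-assay Ct availability.

    ``problems`` lists every (pair, assay, sample) with no usable Ct;
    a pair is callable only when every panel assay has at least one
    non-missing replicate in both its tumour and its control sample.
    """

    problems: list[dict] = field(default_factory=list)
    pair_callable: dict[str, bool] = field(default_factory=dict)

    @property
    def run_callable(self) -> bool:
        return all(self.pair_callable.values()) if self.pair_callable else False

    def to_dict(self) -> dict:
        return {
            "run_callable": self.run_callable,
            "pair_callable": dict(sorted(self.pair_callable.items())),
            "problems": list(self.problems),
        }

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_run(
    ct: CtTable,
    pairs,
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> ValidationReport:
    """Check that every panel assay is measurable in every sample pair.

    Pure report: identical inputs always yield identical reports, and no
    exception is raised for incomplete data.
    """
    report = ValidationReport()
    for pair in pairs:
        ok = True
        for assay in panel.names:
            for which, sample_id in (
                ("tumour", pair.tumour_sample_id),
                ("control", pair.control_sample_id),
            ):
                if not ct.has_signal(sample_id, assay, config.max_ct):
                    ok = False
                    report.problems.append(
                        {
                            "patient_id": pair.patient_id,
                            "assay": assay,
                            "sample_id": sample_id,
                            "role": which,
                        }
                    )
        report.pair_callable[pair.patient_id] = ok
    return report
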