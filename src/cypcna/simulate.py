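"""Synthetic Ct tables with known copy-number ground truth.

The generator writes the measurement process backwards: a tumour is a
mixture of a fraction ``f`` of tumour cells carrying the configured copy
numbers and ``1 - f`` stromal diploid cells, so the effective template for
gene g is

    m_g(tumour)  = f * CN_g + (1 - f) * 2        (copies per cell)
    m_g(control) = 2

and each replicate threshold cycle is

    Ct = B_g + dose_offset - log2(m_g / 2) + eps,   eps ~ Normal(0, sigma^2)

with a fixed per-assay baseline B_g (cycles) and a per-sample template-dose
offset.  Noise is Gaussian on the cycle scale — Ct is the measured
quantity — which corresponds to multiplicative lognormal noise on template
amount.  A gene with zero effective template never amplifies and its Ct is
emitted as missing.  Preamplification is treated as part of the dose
offset; an unbiased preamp shifts every assay of a sample equally and
cancels in the ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cna_caller import NO_CALL, CallingConfig, call_pair
from .errors import SchemaError, TooFewReferencesError
from .panel_io import CtTable, Panel, SamplePair, default_panel

#: Fixed per-assay baseline Ct values (cycles) so fixtures are stable.
#: Magnitudes are typical of post-preamplification genomic DNA input.
DEFAULT_BASELINE_CT: dict[str, float] = {
    "RPPH1": 24.5,
    "ALB": 23.1,
    "B2M": 22.7,
    "BCKDHA": 26.0,
    "CD36": 25.2,
    "F5": 24.0,
    "MPO": 23.6,
    "TBP": 26.4,
    "CYP3A4": 25.8,
    "CYP2C8": 24.9,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of a simulated cohort.

    ``true_cn`` maps assay name -> tumour-cell copy number (unlisted assays
    are diploid).  ``correlated_events`` applies one copy number jointly to
    a set of assays (arm-level events such as a 1q gain carrying F5).
    """

    panel: Panel = field(default_factory=default_panel)
    baseline_ct: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_CT))
    true_cn: dict = field(default_factory=dict)
    tumour_cell_fraction: float = 1.0
    tumour_dose_offset: float = 0.0
    control_dose_offset: float = 0.0
    noise_sd: float = 0.0
    replicates: int = 2
    n_patients: int = 1
    seed: int = 0
    correlated_events: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.tumour_cell_fraction <= 1.0):
            raise SchemaError("tumour_cell_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SchemaError("replicates must be >= 1")
        for name in self.true_cn:
            if name not in self.panel:
                raise SchemaError(f"true_cn gene {name!r} is not in the panel")
        for genes, _cn in self.correlated_events:
            for name in genes:
                if name not in self.panel:
                    raise SchemaError(
                        f"correlated event gene {name!r} is not in the panel"
                    )
        for assay in self.panel:
            if assay.name not in self.baseline_ct:
                raise SchemaError(f"no baseline Ct for assay {assay.name!r}")

    def resolved_cn(self) -> dict[str, float]:
        """Tumour-cell copy number per assay after applying correlated events."""
        cn = {a.name: 2.0 for a in self.panel}
        cn.update({k: float(v) for k, v in self.true_cn.items()})
        for genes, value in self.correlated_events:
            for name in genes:
                cn[name] = float(value)
        return cn

    def mixture_cn(self) -> dict[str, float]:
        """Population-average copies per cell in the tumour sample."""
        f = self.tumour_cell_fraction
        return {g: f * cn + (1.0 - f) * 2.0 for g, cn in self.resolved_cn().items()}


def simulate_pair(
    config: SimulationConfig,
    patient_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[CtTable, dict]:
    """Simulate one tumour/control pair.

    Returns the Ct table (samples ``<patient>_T`` and ``<patient>_C``) and a
    ground-truth record mapping assay name to its tumour-cell and
    population-average copy numbers.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tumour_id, control_id = f"{patient_id}_T", f"{patient_id}_C"
    mixture = config.mixture_cn()
    truth = {
        g: {"true_cn": cn, "mixture_cn": mixture[g]}
        for g, cn in config.resolved_cn().items()
    }

    rows = []
    for assay in config.panel:
        base = config.baseline_ct[assay.name]
        for sample_id, m, dose in (
            (tumour_id, mixture[assay.name], config.tumour_dose_offset),
            (control_id, 2.0, config.control_dose_offset),
        ):
            for rep in range(1, config.replicates + 1):
                if m <= 0.0:
                    ct = np.nan  # homozygous null: no template, no amplification
                else:
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                    ct = base + dose - np.log2(m / 2.0) + eps
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": assay.gene,
                        "allele_label": assay.allele_label or "",
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return CtTable(pd.DataFrame(rows), config.panel), truth


@dataclass
class CohortSim:
    """A simulated cohort: Ct table, sample pairs, and per-gene truth."""

    ct: CtTable
    pairs: list[SamplePair]
    truth: pd.DataFrame


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate ``n_patients`` independent tumour/control pairs.

    All patients share one ground-truth profile; the random stream is a
    single generator seeded from ``config.seed`` so the cohort is
    reproducible end to end.
    """
    rng = np.random.default_rng(config.seed)
    frames, pairs, truth_rows = [], [], []
    for i in range(1, config.n_patients + 1):
        patient = f"P{i:03d}"
        table, truth = simulate_pair(config, patient, rng)
        frames.append(table.data[["sample_id", "gene", "allele_label", "replicate", "ct"]])
        pairs.append(
            SamplePair(
                patient_id=patient,
                tumour_sample_id=f"{patient}_T",
                control_sample_id=f"{patient}_C",
                control_kind="blood",
            )
        )
        for gene, rec in truth.items():
            truth_rows.append({"patient_id": patient, "gene": gene, **rec})
    ct = CtTable(pd.concat(frames, ignore_index=True), config.panel)
    return CohortSim(ct=ct, pairs=pairs, truth=pd.DataFrame(truth_rows))


@dataclass
class RecoveryReport:
    """Bias/RMSE of recovered copy numbers and call accuracy on a cohort."""

    per_gene: pd.DataFrame
    sensitivity: float  # truly altered (population-average != 2) and called
    specificity: float  # truly unaltered and not called
    n_reps: int
    n_uncallable: int = 0  # pairs where reference validation failed


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    calling_config: CallingConfig = CallingConfig(),
    alteration_eps: float = 1e-9,
) -> RecoveryReport:
    """Simulate ``n_reps`` pairs and measure how well the caller recovers them.

    The estimand is the population-average copy number ``m_g`` (the mixture
    of tumour and stromal cells), which is what relative quantification can
    see.  Sensitivity counts truly altered (gene, patient) instances whose
    call is not ``none``; specificity counts truly diploid instances whose
    call is ``none``.
    """
    sim_config = replace(config, n_patients=n_reps)
    cohort = simulate_cohort(sim_config)
    mixture = sim_config.mixture_cn()

    estimates: dict[str, list[float]] = {g: [] for g in mixture}
    tp = fn = tn = fp = 0
    n_uncallable = 0
    for pair in cohort.pairs:
        try:
            result = call_pair(cohort.ct, pair, sim_config.panel, calling_config)
        except TooFewReferencesError:
            # at high noise a pair can fail reference validation; report it
            # rather than abort the experiment
            n_uncallable += 1
            continue
        for row in result.table.itertuples():
            estimates[row.gene].append(row.copy_number)
            altered = abs(mixture[row.gene] - 2.0) > alteration_eps
            called = row.call != NO_CALL
            if altered and called:
                tp += 1
            elif altered:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1

    rows = []
    for gene, est in estimates.items():
        est = np.asarray(est)
        if len(est) == 0:
            rows.append(
                {"gene": gene, "true_mixture_cn": mixture[gene],
                 "mean_estimate": float("nan"), "bias": float("nan"),
                 "rmse": float("nan"), "n": 0}
            )
            continue
        rows.append(
            {
                "gene": gene,
                "true_mixture_cn": mixture[gene],
                "mean_estimate": float(est.mean()),
                "bias": float(est.mean() - mixture[gene]),
                "rmse": float(np.sqrt(((est - mixture[gene]) ** 2).mean())),
                "n": len(est),
            }
        )
    return RecoveryReport(
        per_gene=pd.DataFrame(rows),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        n_reps=n_reps,
        n_uncallable=n_uncallable,
    )
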