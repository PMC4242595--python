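"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

MARKERS = ("ALDH2", "CCNE1", "SMAD3")
#: risk-carrying expression state per marker: ALDH2 loss is adverse,
#: CCNE1 / SMAD3 gain is adverse
MARKER_RISK_STATE = {"ALDH2": "low", "CCNE1": "high", "SMAD3": "high"}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale analogue of a 10-patient paired
    tumor/normal DGE screen plus a 103-patient IHC validation cohort:
    500 genes at 5e4 clean tags per library instead of ~17,000 genes at
    ~3.5M tags, with identical statistical structure.

    Attributes
    ----------
    seed : int
        Base seed; identical seeds give byte-identical outputs.
    n_genes : int
        Genes (one transcript each) in the synthetic annotation.
    n_patients : int
        Paired tumor/normal patients in the expression screen.
    library_size : int
        Expected clean-tag total per library.
    de_fraction : float
        Fraction of genes planted as differentially expressed.
    planted_log2fc : float
        Absolute log2 fold change of planted genes (sign fixed per gene).
    recurrence : float
        Fraction of patients in which a planted effect is applied
        (default 0.7, i.e. 7 of 10 -- both sides of the ">=5 cases"
        recurrence rule are exercised by sampling variation).
    nb_dispersion : float
        Negative-binomial size parameter k (variance mu + mu^2/k) of the
        marginal per-gene counts; the biological gamma draw is shared
        within a patient pair so that the tumor/normal sampling is
        conditionally Poisson.
    tag_error_rate : float
        Per-base substitution probability when emitting tag sequences.
    abundance_meanlog, abundance_sdlog : float
        Log-normal distribution of relative gene abundances.
    cohort_size : int
        Patients in the survival cohort.
    marker_log_hr : float
        Per-marker log hazard ratio of the adverse expression state.
    marker_latent_rho : float
        Squared loading of the shared latent risk factor on each marker
        (drives the marker-marker correlation of the cohort).
    censor_rate : float
        Target fraction of administratively censored patients.
    baseline_hazard : float
        Exponential event rate (per month) of a patient with no adverse
        marker state.
    """

    seed: int = 0
    n_genes: int = 500
    n_patients: int = 10
    library_size: int = 50_000
    de_fraction: float = 0.1
    planted_log2fc: float = 3.0
    recurrence: float = 0.7
    nb_dispersion: float = 10.0
    tag_error_rate: float = 0.002
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.0
    cohort_size: int = 103
    marker_log_hr: float = 1.0
    marker_latent_rho: float = 0.5
    censor_rate: float = 0.3
    baseline_hazard: float = 0.008

    def validate(self) -> None:
        for name in ("de_fraction", "recurrence", "tag_error_rate",
                     "censor_rate", "marker_latent_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_genes", "n_patients", "library_size", "cohort_size"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name}={v} must be a positive integer")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1 when nonzero")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """Thresholds, paths, and seeds of a pipeline run."""

    outdir: str = "dgekit_run"
    seed: int = 0
    fold_threshold: float = 1.0
    fdr_threshold: float = 0.001
    min_cases: int | None = None       # None -> ceil(n_patients / 2)
    min_avg_fold: float = 1.0
    tpm_denominator: str = "unique"    # "unique" or "clean"
    staining_cutoff: int = 5
    staining_combine: str = "product"  # or "sum"
    recurrence_over: str = "all"       # mean log2ratio over "all" or "de" pairs
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # optional external inputs (paths); when unset the simulator is used
    genome_fasta: str | None = None
    annotation_bed: str | None = None
    tag_dir: str | None = None
    clinical_table: str | None = None

    def validate(self) -> None:
        if self.fold_threshold < 0 or self.fdr_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.tpm_denominator not in ("unique", "clean"):
            raise ValueError("tpm_denominator must be 'unique' or 'clean'")
        if self.staining_combine not in ("product", "sum"):
            raise ValueError("staining_combine must be 'product' or 'sum'")
        if self.recurrence_over not in ("all", "de"):
            raise ValueError("recurrence_over must be 'all' or 'de'")
        for p in (self.genome_fasta, self.annotation_bed, self.clinical_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        self.simulation.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig.from_dict(sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(simulation=sim, **d)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
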