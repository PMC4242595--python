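"""Synthetic genomes, tag libraries, paired count studies, and survival cohorts.

The generators emulate the statistical structure of a paired
tumor/normal DGE screen at desk scale: log-normal gene abundances,
negative-binomial tag counts realized as gamma-Poisson with the
biological (gamma) draw shared between the tumor and normal library of a
patient so the within-pair sampling is conditionally Poisson, planted
differentially expressed genes with a per-gene sign applied in a subset
of patients, per-base substitution errors on emitted tags, and a
survival cohort whose three dichotomized markers load on one shared
latent risk factor that multiplies an exponential event hazard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgekit.config import MARKERS, MARKER_RISK_STATE, SimulationConfig
from dgekit.reference import DOWNSTREAM, SITE, TAG_LEN, TagCatalog

__all__ = [
    "CountStudy",
    "simulate_genome",
    "simulate_paired_counts",
    "simulate_tags",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CountStudy:
    """Paired tumor/normal gene-count tables with planted-truth bookkeeping."""

    normal: pd.DataFrame          # genes x patients
    tumor: pd.DataFrame           # genes x patients
    library_size: int
    truth: pd.DataFrame = field(default=None)  # per-gene is_de, log2fc, n_affected

    @property
    def gene_ids(self) -> list[str]:
        return list(self.normal.index)

    @property
    def patients(self) -> list[str]:
        return list(self.normal.columns)


def simulate_genome(n_chrom: int, chrom_length: int, n_transcripts: int,
                    seed: int, tx_length: tuple[int, int] = (120, 400),
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus transcript annotation with usable NlaIII sites.

    Transcripts are placed without overlap on random strands; any
    transcript lacking a sense-strand CATG with 17 downstream bases
    inside its span gets one planted, so every transcript can carry a
    canonical tag.  Returns (chrom -> sequence, BED-like annotation
    with transcript and gene ids; one gene per transcript).
    """
    if chrom_length < 200:
        raise ValueError("chrom_length must be >= 200")
    rng = np.random.default_rng(seed)
    lo, hi = tx_length
    lo = max(lo, TAG_LEN + 4)
    if hi > chrom_length:
        hi = chrom_length
    # keep occupancy below ~half the genome so placement terminates;
    # shrink transcripts rather than fail when many are requested
    budget = max(TAG_LEN + 4, n_chrom * chrom_length // max(1, 2 * n_transcripts))
    hi = min(hi, max(lo, budget))
    lo = min(lo, hi)
    if lo > chrom_length:
        raise ValueError(
            f"transcripts (min length {lo}) do not fit a {chrom_length} bp chromosome"
        )

    genome = {
        f"chr{c + 1}": "".join(rng.choice(_BASES, size=chrom_length))
        for c in range(n_chrom)
    }

    # non-overlapping placement, round-robin over chromosomes
    slots: list[tuple[str, int, int]] = []
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    chroms = sorted(genome)
    attempts = 0
    while len(slots) < n_transcripts:
        attempts += 1
        if attempts > 200 * n_transcripts:
            raise ValueError(
                f"cannot place {n_transcripts} non-overlapping transcripts of "
                f"{lo}-{hi} bp on {n_chrom} x {chrom_length} bp"
            )
        chrom = chroms[len(slots) % len(chroms)]
        length = int(rng.integers(lo, hi + 1))
        if length > chrom_length:
            continue
        start = int(rng.integers(0, chrom_length - length + 1))
        end = start + length
        if any(not (end <= s or start >= e) for s, e in per_chrom[chrom]):
            continue
        per_chrom[chrom].append((start, end))
        slots.append((chrom, start, end))

    records = []
    for i, (chrom, start, end) in enumerate(slots):
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[chrom]
        sense = seq[start:end]
        if strand == "-":
            from dgekit.reference import reverse_complement

            sense = reverse_complement(sense)
        # usable site: CATG with DOWNSTREAM bases following it in sense coords
        usable = any(
            sense[p : p + 4] == SITE
            for p in range(0, len(sense) - TAG_LEN + 1)
        )
        if not usable:
            # plant a CATG in sense coordinates, leaving 17 bp downstream
            p = int(rng.integers(0, len(sense) - TAG_LEN + 1))
            sense = sense[:p] + SITE + sense[p + 4 :]
            if strand == "+":
                seq = seq[:start] + sense + seq[end:]
            else:
                from dgekit.reference import reverse_complement

                seq = seq[:start] + reverse_complement(sense) + seq[end:]
            genome[chrom] = seq
        records.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "transcript_id": f"TX{i + 1:04d}",
                "strand": strand,
                "gene_id": f"G{i + 1:04d}",
            }
        )
    annotation = pd.DataFrame(records)
    return genome, annotation


def simulate_paired_counts(config: SimulationConfig) -> CountStudy:
    """Paired tumor/normal negative-binomial gene counts with planted DEGs.

    Per gene a relative abundance is drawn log-normally and scaled so
    expected library totals equal ``library_size``.  A ``de_fraction``
    subset of genes receives a tumor effect of +/- ``planted_log2fc``
    (sign fixed per gene) applied in ``ceil(recurrence * n_patients)``
    randomly chosen patients; tumor means are renormalized per library,
    so planted effects induce the compositional shift real libraries
    show.  Marginal counts are NB with size ``nb_dispersion``; the
    biological draw is shared within each pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, P = config.n_genes, config.n_patients
    genes = [f"G{i + 1:04d}" for i in range(G)]
    patients = [f"P{j + 1:02d}" for j in range(P)]

    mu_rel = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, size=G)
    mu = mu_rel / mu_rel.sum() * config.library_size

    n_de = int(round(config.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = np.zeros(G)
    if n_de:
        signs[de_idx] = rng.choice([-1.0, 1.0], size=n_de)
    beta = signs * config.planted_log2fc

    n_affected = math.ceil(config.recurrence * P) if n_de else 0
    affected = np.zeros((G, P), dtype=bool)
    for g in de_idx:
        affected[g, rng.choice(P, size=n_affected, replace=False)] = True

    if np.any((mu < 1.0) & (beta != 0.0)):
        warnings.warn(
            "library_size too small to realize some planted gene means (< 1 tag)",
            stacklevel=2,
        )

    k = config.nb_dispersion
    normal = np.empty((G, P), dtype=np.int64)
    tumor = np.empty((G, P), dtype=np.int64)
    for j in range(P):
        lam = rng.gamma(shape=k, scale=mu / k)          # shared biological draw
        fc = np.where(affected[:, j], 2.0 ** beta, 1.0)
        tumor_mean = lam * fc
        # renormalize so the expected tumor total equals library_size
        scale = (mu * fc).sum()
        tumor_mean = tumor_mean * (config.library_size / scale)
        normal[:, j] = rng.poisson(lam)
        tumor[:, j] = rng.poisson(tumor_mean)

    truth = pd.DataFrame(
        {
            "is_de": signs != 0.0,
            "log2fc": beta,
            "sign": np.sign(beta).astype(int),
            "n_affected": affected.sum(axis=1),
        },
        index=genes,
    )
    return CountStudy(
        normal=pd.DataFrame(normal, index=genes, columns=patients),
        tumor=pd.DataFrame(tumor, index=genes, columns=patients),
        library_size=config.library_size,
        truth=truth,
    )


def _mutate_tags(tag: str, n_copies: int, error_rate: float,
                 rng: np.random.Generator) -> dict[str, int]:
    """Emit ``n_copies`` of ``tag`` with independent per-base substitutions."""
    out: dict[str, int] = {}
    if n_copies == 0:
        return out
    if error_rate == 0.0:
        return {tag: n_copies}
    n_err_bases = rng.binomial(TAG_LEN, error_rate, size=n_copies)
    clean = int((n_err_bases == 0).sum())
    if clean:
        out[tag] = clean
    for n_err in n_err_bases[n_err_bases > 0]:
        pos = rng.choice(TAG_LEN, size=int(n_err), replace=False)
        chars = list(tag)
        for p in pos:
            alt = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alt[int(rng.integers(0, 3))]
        mutated = "".join(chars)
        out[mutated] = out.get(mutated, 0) + 1
    return out


def simulate_tags(count_study: CountStudy, catalog: TagCatalog,
                  tag_error_rate: float, seed: int) -> dict[str, dict[str, int]]:
    """Emit per-library tag lists from gene counts via canonical catalog tags.

    Every gene's canonical 21-bp tag is emitted with multiplicity equal
    to its count; each base is substituted independently with
    probability ``tag_error_rate``.  Returns library id -> {tag: count};
    library ids are ``<patient>_normal`` / ``<patient>_tumor``.
    """
    tag_by_gene: dict[str, str] = {}
    for t in catalog.tags:
        if t.is_canonical and t.gene_id is not None and t.gene_id not in tag_by_gene:
            tag_by_gene[t.gene_id] = t.sequence
    missing = [g for g in count_study.gene_ids if g not in tag_by_gene]
    if missing:
        raise ValueError(
            f"genes without a canonical tag in the catalog: {missing[:10]}"
        )

    rng = np.random.default_rng(seed)
    libraries: dict[str, dict[str, int]] = {}
    for kind, table in (("normal", count_study.normal), ("tumor", count_study.tumor)):
        for patient in table.columns:
            lib: dict[str, int] = {}
            for gene, count in table[patient].items():
                for t, c in _mutate_tags(
                    tag_by_gene[gene], int(count), tag_error_rate, rng
                ).items():
                    lib[t] = lib.get(t, 0) + c
            libraries[f"{patient}_{kind}"] = dict(sorted(lib.items()))
    return libraries


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic survival cohort with three correlated dichotomized markers.

    A standard-normal latent risk factor per patient loads on each
    marker's staining read-out (loading sqrt(marker_latent_rho); the
    ALDH2 analogue loads negatively, so its LOW state tracks risk) and
    on T stage.  The event hazard is exponential:
    ``baseline_hazard * exp(marker_log_hr * n_adverse_states)``.
    Censoring is independent exponential, calibrated to the configured
    rate.  Columns: patient_id, sex, age, t_stage, per-marker
    proportion_pct and intensity_grade, time (months), event.
    """
    config.validate()
    if config.cohort_size < 10:
        raise ValueError("cohort_size must be >= 10")
    rng = np.random.default_rng(config.seed + 1)
    n = config.cohort_size
    z = rng.normal(size=n)
    rho = config.marker_latent_rho

    records: dict[str, np.ndarray | list] = {
        "patient_id": [f"C{i + 1:03d}" for i in range(n)],
        "sex": np.where(rng.random(n) < 0.75, "Male", "Female"),
        "age": rng.integers(32, 88, size=n),
    }

    # intensity grows with the latent percentile; the proportion bin and
    # grade cross index >= 5 ("high") near the median
    def staining_from_u(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pct = np.clip(100.0 * u, 0.0, 100.0)
        grade = np.select(
            [u < 0.15, u < 0.5, u < 0.8], [0, 1, 2], default=3
        )
        return pct, grade

    from scipy.stats import norm

    n_adverse = np.zeros(n, dtype=int)
    for m in MARKERS:
        loading = -math.sqrt(rho) if MARKER_RISK_STATE[m] == "low" else math.sqrt(rho)
        latent = loading * z + math.sqrt(1.0 - rho) * rng.normal(size=n)
        u = norm.cdf(latent)
        pct, grade = staining_from_u(u)
        records[f"{m}_proportion_pct"] = np.round(pct, 1)
        records[f"{m}_intensity_grade"] = grade
        high = (np.select(
            [pct == 0, pct <= 5, pct <= 25, pct <= 50, pct <= 75],
            [0, 1, 2, 3, 4], default=5) * grade) >= 5
        adverse = ~high if MARKER_RISK_STATE[m] == "low" else high
        n_adverse += adverse.astype(int)

    # T stage correlated with the shared latent risk
    t_latent = 0.6 * z + 0.8 * rng.normal(size=n)
    q60, q75 = np.quantile(t_latent, [0.60, 0.75])
    records["t_stage"] = np.select(
        [t_latent < q60, t_latent < q75], ["T1", "T2"], default="T3"
    )

    hazard = config.baseline_hazard * np.exp(config.marker_log_hr * n_adverse)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_hazard = (
            config.censor_rate / (1.0 - config.censor_rate) * hazard.mean()
        )
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    records["time"] = np.round(np.maximum(time, 1.0 / 30.0), 2)  # months, > 0
    records["event"] = (event_time <= censor_time).astype(int)
    return pd.DataFrame(records)
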