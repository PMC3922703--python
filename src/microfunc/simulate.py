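"""Synthetic functional-gene chip datasets with known ground truth.

Emulates the structure of a two-group (healthy ``H`` vs caries-active
``C``) saliva-microbiota chip experiment: a fixed set of *core* genes
present in every sample, *non-core* genes whose per-gene presence
probability varies across the gene pool and is shifted between groups on
the logit scale, a few *exclusive* genes absent from one group entirely,
and planted discriminative gene *triplets*.  Present genes receive
lognormal signal intensities and SNRs; absent genes receive low background
intensity and an SNR below the calling cutoff, so the positive-calling
filter is actually exercised.

The default configuration reproduces the scale of the study population it
emulates: 10+10 samples, ~3,600-3,700 genes detectable in at least one
sample, per-sample richness around 2,250-2,900, and a group functional
core of roughly 35% of the group's gene pool.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from .dataset import PATHWAY_GROUPS, SignalDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CATEGORIES",
    "generate_annotation",
    "simulate_dataset",
    "write_dataset",
    "detection_prob_given_present",
    "expected_richness",
]

#: The 19 functional-gene categories carried by the chip model.
CATEGORIES: tuple[str, ...] = (
    "Amino acid synthesis",
    "Amino acid transport and metabolism",
    "Central Carbon Metabolism Pathways",
    "Cofactor Biosynthesis",
    "Complex Carbohydrates",
    "Feeder Pathways to Glycolysis",
    "Respiration",
    "Nitrogen Metabolism",
    "Pyrimidine metabolism",
    "Purine metabolism",
    "Fatty Acid Metabolism",
    "Fatty Acid Biosynthesis",
    "Organic Acids",
    "Glycan Biosynthesis and Metabolism",
    "Glycosaminoglycan degradation",
    "Glycan structures - degradation",
    "Isoprenoid biosynthesis",
    "Exotic Metabolisms",
    "Sulfur Metabolism",
)

# Intensity-mass shares of the most prominent categories; the remainder is
# spread uniformly.  (Amino acid synthesis ~25%, AA transport ~15%, central
# carbon ~10%, cofactor biosynthesis ~8%, complex carbohydrates ~7%.)
_PROMINENT = {
    "Amino acid synthesis": 0.25,
    "Amino acid transport and metabolism": 0.15,
    "Central Carbon Metabolism Pathways": 0.10,
    "Cofactor Biosynthesis": 0.08,
    "Complex Carbohydrates": 0.07,
}


def _default_weights() -> tuple[float, ...]:
    rest = (1.0 - sum(_PROMINENT.values())) / (len(CATEGORIES) - len(_PROMINENT))
    return tuple(_PROMINENT.get(c, rest) for c in CATEGORIES)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic chip generator.

    Presence model: a fraction ``core_fraction`` of genes is present in all
    samples; the remaining genes draw a per-gene baseline presence
    probability from a Beta distribution with mean
    ``noncore_presence_baseline`` and concentration
    ``presence_concentration`` (small values give a U-shaped mix of
    near-ubiquitous and rare genes, which is what keeps the detectable gene
    pool finite), then receive a group-specific logit shift of
    ``±group_effect/2`` with a random per-gene direction.

    Signal model: present genes draw intensity from
    lognormal(``intensity_log_mean``, ``intensity_log_sd``) and SNR from
    lognormal(``snr_log_mean``, ``snr_log_sd``); a present gene can
    therefore still fall below the calling cutoffs (detection thinning),
    except core and planted-marker genes, whose present entries are drawn
    above both cutoffs so the planted structure is exactly recoverable.
    Absent genes draw background intensity around
    ``background_intensity_mean`` and an SNR clipped below ``snr_cutoff``.
    """

    n_samples_per_group: int = 10
    n_genes: int = 5400
    n_categories: int = 19
    category_weights: tuple = field(default_factory=_default_weights)
    n_families: int = 139
    core_fraction: float = 0.205
    noncore_presence_baseline: float = 0.42
    presence_concentration: float = 0.3
    group_effect: float = 1.0
    n_exclusive_per_group: int = 2
    exclusive_presence: float = 0.9
    n_planted_triplets_per_group: int = 2
    triplet_presence_high: float = 0.95
    triplet_presence_low: float = 0.05
    intensity_log_mean: float = 8.0
    intensity_log_sd: float = 1.0
    snr_log_mean: float = float(np.log(10.0))
    snr_log_sd: float = 0.8
    background_intensity_mean: float = 200.0
    background_log_sd: float = 0.5
    intensity_cutoff: float = 1000.0
    snr_cutoff: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "core_fraction": self.core_fraction,
            "noncore_presence_baseline": self.noncore_presence_baseline,
            "exclusive_presence": self.exclusive_presence,
            "triplet_presence_high": self.triplet_presence_high,
            "triplet_presence_low": self.triplet_presence_low,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        w = np.asarray(self.category_weights, dtype=float)
        if len(w) != self.n_categories:
            raise ValueError(
                f"category_weights has length {len(w)}, expected {self.n_categories}"
            )
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("category_weights must sum to 1")
        if (w < 0).any():
            raise ValueError("category_weights must be nonnegative")
        n_planted = 3 * self.n_planted_triplets_per_group + self.n_exclusive_per_group
        n_noncore = self.n_genes - int(round(self.core_fraction * self.n_genes))
        if n_noncore < 2 * n_planted:
            raise ValueError(
                "n_genes leaves too few non-core genes for the planted structure"
            )
        if self.presence_concentration <= 0:
            raise ValueError("presence_concentration must be positive")
        if self.group_effect < 0:
            raise ValueError("group_effect must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    core_gene_ids: list
    exclusive_gene_ids_by_group: dict
    planted_triplets_by_group: dict
    per_gene_presence_prob: pd.DataFrame  # genes x groups

    def __post_init__(self) -> None:
        groups = list(self.per_gene_presence_prob.columns)
        for grp, genes in self.exclusive_gene_ids_by_group.items():
            others = [g for g in groups if g != grp]
            for gene in genes:
                if any(self.per_gene_presence_prob.loc[gene, o] > 0 for o in others):
                    raise ValueError(f"exclusive gene {gene} present in other group")
        core = set(self.core_gene_ids)
        for triplets in self.planted_triplets_by_group.values():
            for t in triplets:
                if core & set(t):
                    raise ValueError("planted triplet contains a core gene")


def _rngs(config: SimulationConfig):
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _category_names(config: SimulationConfig) -> list[str]:
    if config.n_categories <= len(CATEGORIES):
        return list(CATEGORIES[: config.n_categories])
    extra = [f"Category {i}" for i in range(len(CATEGORIES) + 1, config.n_categories + 1)]
    return list(CATEGORIES) + extra


def _pathway_group(category: str) -> str:
    for grp, cats in PATHWAY_GROUPS.items():
        if category in cats:
            return grp
    return "Other"


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene annotation table: family, category, pathway group.

    Categories are drawn i.i.d. per ``category_weights``; the gene-family
    pool (139 families by default) is allocated to categories by largest
    remainder so richer categories carry more families.  Deterministic for
    a fixed config seed.
    """
    rng, _ = _rngs(config)
    names = _category_names(config)
    w = np.asarray(config.category_weights, dtype=float)
    cat_idx = rng.choice(config.n_categories, size=config.n_genes, p=w)

    # largest-remainder allocation of the family pool over categories
    raw = w * config.n_families
    alloc = np.floor(raw).astype(int)
    alloc = np.maximum(alloc, 1)
    while alloc.sum() > config.n_families and (alloc > 1).any():
        alloc[np.argmax(alloc)] -= 1
    rem = config.n_families - alloc.sum()
    if rem > 0:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        for i in range(rem):
            alloc[order[i % len(order)]] += 1

    fam_idx = np.array([rng.integers(alloc[c]) for c in cat_idx])
    width = len(str(config.n_genes))
    genes = [f"gene_{i + 1:0{width}d}" for i in range(config.n_genes)]
    table = pd.DataFrame(
        {
            "family": [f"{names[c]} family {j + 1}" for c, j in zip(cat_idx, fam_idx)],
            "category": [names[c] for c in cat_idx],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["pathway_group"] = [_pathway_group(c) for c in table["category"]]
    return table


def detection_prob_given_present(config: SimulationConfig) -> float:
    """P(intensity >= cutoff and SNR >= cutoff | gene present), closed form.

    Both signals are lognormal, so each marginal is a normal survival
    probability on the log scale; the two draws are independent.  Core and
    planted-marker genes are exempt from thinning (their present entries
    are truncated above the cutoffs).
    """
    p_int = norm.sf(
        (np.log(config.intensity_cutoff) - config.intensity_log_mean)
        / config.intensity_log_sd
    ) if config.intensity_log_sd > 0 else float(
        config.intensity_log_mean >= np.log(config.intensity_cutoff)
    )
    p_snr = norm.sf(
        (np.log(config.snr_cutoff) - config.snr_log_mean) / config.snr_log_sd
    ) if config.snr_log_sd > 0 else float(config.snr_log_mean >= np.log(config.snr_cutoff))
    return float(p_int * p_snr)


def expected_richness(
    ground_truth: GroundTruth, config: SimulationConfig, group: str
) -> tuple[float, float]:
    """Expected detected-gene count per sample of ``group`` and its sd.

    Conditional on the planted per-gene presence probabilities, each
    gene's detection in one sample is Bernoulli(p_g * q_g) with q_g the
    closed-form detection probability given presence (1 for core and
    planted-marker genes).  Returns (mean, sd) of the per-sample richness.
    """
    p = ground_truth.per_gene_presence_prob[group].to_numpy(copy=True)
    q = np.full_like(p, detection_prob_given_present(config))
    exempt = set(ground_truth.core_gene_ids)
    for genes in ground_truth.exclusive_gene_ids_by_group.values():
        exempt |= set(genes)
    for triplets in ground_truth.planted_triplets_by_group.values():
        for t in triplets:
            exempt |= set(t)
    is_exempt = np.array(
        [g in exempt for g in ground_truth.per_gene_presence_prob.index]
    )
    q[is_exempt] = 1.0
    d = p * q
    return float(d.sum()), float(np.sqrt((d * (1 - d)).sum()))


def _truncated_lognormal(rng, log_mean, log_sd, lower, size) -> np.ndarray:
    """Lognormal draws conditioned on exceeding ``lower``."""
    if log_sd <= 0:
        return np.full(size, np.exp(log_mean))
    a = (np.log(lower) - log_mean) / log_sd
    return np.exp(
        truncnorm.rvs(a, np.inf, loc=log_mean, scale=log_sd, size=size, random_state=rng)
    )


def simulate_dataset(config: SimulationConfig) -> tuple[SignalDataset, GroundTruth]:
    """Draw one synthetic chip dataset plus its ground truth.

    Deterministic given the config (all randomness flows from
    ``config.seed``).  Core genes are detected in every sample after
    positive calling at the config's cutoffs; exclusive genes have zero
    detections in their off group.
    """
    annotation = generate_annotation(config)
    _, rng = _rngs(config)
    genes = annotation.index
    n = config.n_genes
    n_per = config.n_samples_per_group
    groups = ("H", "C")
    samples = [f"H{i + 1:02d}" for i in range(n_per)] + [
        f"C{i + 1:02d}" for i in range(n_per)
    ]
    sample_group = np.array(["H"] * n_per + ["C"] * n_per)

    # --- assign gene roles -------------------------------------------------
    perm = rng.permutation(n)
    n_core = int(round(config.core_fraction * n))
    core_idx = np.sort(perm[:n_core])
    pool = perm[n_core:]
    cursor = 0
    exclusive_idx = {}
    for grp in groups:
        exclusive_idx[grp] = np.sort(pool[cursor : cursor + config.n_exclusive_per_group])
        cursor += config.n_exclusive_per_group
    triplet_idx = {}
    for grp in groups:
        trips = []
        for _ in range(config.n_planted_triplets_per_group):
            trips.append(np.sort(pool[cursor : cursor + 3]))
            cursor += 3
        triplet_idx[grp] = trips

    # --- per-gene presence probabilities -----------------------------------
    m = config.noncore_presence_baseline
    kappa = config.presence_concentration
    baseline = rng.beta(m * kappa, (1 - m) * kappa, size=n)
    baseline = np.clip(baseline, 1e-6, 1 - 1e-6)
    sign = rng.choice([-1.0, 1.0], size=n)
    shift = sign * config.group_effect / 2.0
    prob = {
        "H": expit(logit(baseline) + shift),
        "C": expit(logit(baseline) - shift),
    }
    for grp in groups:
        prob[grp][core_idx] = 1.0
    for grp in groups:
        other = "C" if grp == "H" else "H"
        prob[grp][exclusive_idx[grp]] = config.exclusive_presence
        prob[other][exclusive_idx[grp]] = 0.0
        for t in triplet_idx[grp]:
            prob[grp][t] = config.triplet_presence_high
            prob[other][t] = config.triplet_presence_low

    # --- presence draws ----------------------------------------------------
    present = np.zeros((n, 2 * n_per), dtype=bool)
    for j, grp in enumerate(sample_group):
        present[:, j] = rng.random(n) < prob[grp]

    # genes whose present entries are guaranteed above both cutoffs
    exempt = np.zeros(n, dtype=bool)
    exempt[core_idx] = True
    for grp in groups:
        exempt[exclusive_idx[grp]] = True
        for t in triplet_idx[grp]:
            exempt[t] = True

    # --- signal draws ------------------------------------------------------
    intensity = np.exp(
        rng.normal(
            np.log(config.background_intensity_mean) - config.background_log_sd**2 / 2,
            config.background_log_sd,
            size=present.shape,
        )
    )
    snr = np.clip(rng.normal(1.0, 0.3, size=present.shape), 0.05, 0.95 * config.snr_cutoff)

    plain_present = present & ~exempt[:, None]
    n_plain = int(plain_present.sum())
    intensity[plain_present] = np.exp(
        rng.normal(config.intensity_log_mean, config.intensity_log_sd, size=n_plain)
    )
    snr[plain_present] = np.exp(
        rng.normal(config.snr_log_mean, config.snr_log_sd, size=n_plain)
    )
    exempt_present = present & exempt[:, None]
    n_ex = int(exempt_present.sum())
    intensity[exempt_present] = _truncated_lognormal(
        rng, config.intensity_log_mean, config.intensity_log_sd,
        config.intensity_cutoff, n_ex,
    )
    snr[exempt_present] = _truncated_lognormal(
        rng, config.snr_log_mean, config.snr_log_sd, config.snr_cutoff, n_ex
    )

    # --- metadata ----------------------------------------------------------
    dmft = np.concatenate(
        [np.zeros(n_per, dtype=int), rng.integers(6, 11, size=n_per)]
    )
    metadata = pd.DataFrame(
        {
            "group": sample_group,
            "dmft": dmft,
            "gender": rng.choice(["Male", "Female"], size=2 * n_per),
            "age": rng.integers(18, 24, size=2 * n_per),
        },
        index=pd.Index(samples, name="sample"),
    )

    dataset = SignalDataset(
        intensity=pd.DataFrame(intensity, index=genes, columns=samples),
        snr=pd.DataFrame(snr, index=genes, columns=samples),
        annotation=annotation,
        metadata=metadata,
    )
    truth = GroundTruth(
        core_gene_ids=list(genes[core_idx]),
        exclusive_gene_ids_by_group={
            grp: list(genes[exclusive_idx[grp]]) for grp in groups
        },
        planted_triplets_by_group={
            grp: [tuple(genes[t]) for t in triplet_idx[grp]] for grp in groups
        },
        per_gene_presence_prob=pd.DataFrame(
            {grp: prob[grp] for grp in groups}, index=genes
        ),
    )
    return dataset, truth


def write_dataset(
    dataset: SignalDataset, ground_truth: GroundTruth | None, directory
) -> dict:
    """Write the dataset (and optional ground truth) as TSV/JSON files.

    Emits ``intensity.tsv``, ``snr.tsv``, ``annotation.tsv``,
    ``metadata.tsv`` and, when ground truth is given,
    ``ground_truth.json``.  Returns a name -> path mapping.  The TSV
    round-trips losslessly through :func:`microfunc.io.read_dataset`.
    """
    if len(dataset.samples) == 0:
        raise ValueError("dataset has no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("intensity", dataset.intensity),
        ("snr", dataset.snr),
        ("annotation", dataset.annotation),
        ("metadata", dataset.metadata),
    ):
        path = directory / f"{name}.tsv"
        out = frame.copy()
        out.index.name = out.index.name or ("gene" if name != "metadata" else "sample")
        out.to_csv(path, sep="\t")
        paths[name] = path
    if ground_truth is not None:
        path = directory / "ground_truth.json"
        payload = {
            "core_gene_ids": list(ground_truth.core_gene_ids),
            "exclusive_gene_ids_by_group": {
                k: list(v) for k, v in ground_truth.exclusive_gene_ids_by_group.items()
            },
            "planted_triplets_by_group": {
                k: [list(t) for t in v]
                for k, v in ground_truth.planted_triplets_by_group.items()
            },
            "per_gene_presence_prob": {
                grp: ground_truth.per_gene_presence_prob[grp].to_dict()
                for grp in ground_truth.per_gene_presence_prob.columns
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        paths["ground_truth"] = path
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["category_weights"] = list(d["category_weights"])
    return d
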