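"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline expects: two breeds
(a lean reference, LR, and a lard-type comparison, LT) each sequenced as a
single pooled small-RNA library at eight developmental stages (35E-77E
embryonic, 2P-180P postnatal), plus FPKM time courses, 3'-UTR sequences and
an offline gene-gene interaction-score table.

Tag counts: each miRNA gets a baseline relative abundance drawn log-normal
(heavy-tailed, mimicking the dominance of a few miRNAs in real tag data),
and counts are Poisson (or negative-binomial) around
``library_size * abundance``.  A planted breed effect of ``e`` log2 units
at a stage is split symmetrically (x 2^(e/2) in the first breed,
x 2^(-e/2) in the second) so the expected log2 TPM ratio of breed 1 over
breed 2 equals ``e``.

FPKM: each gene's log2 series is a scaled integer model profile plus
Gaussian noise; UTRs are uniform random DNA with seed-complement sites
inserted at recorded positions for the planted (miRNA, gene) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, FpkmMatrix
from .stem import ModelProfile
from .targets import extract_seed, seed_site_motif

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_count_libraries",
    "gen_mirna_sequences",
    "gen_expression_profiles",
    "gen_utr_sequences",
    "gen_interaction_table",
    "DEFAULT_STAGES",
]

DEFAULT_STAGES = ("35E", "49E", "63E", "77E", "2P", "28P", "90P", "180P")

# distinct salts keep the per-generator RNG streams independent
_SALT_COUNTS = 11
_SALT_MIRNA_SEQ = 12
_SALT_UTR = 13
_SALT_FPKM = 14
_SALT_INTERACTIONS = 15


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    ``planted_de`` is a list of ``(mirna_id, stage_collection, log2_effect)``
    triples; the effect is the expected log2 TPM fold of the first breed
    over the second at those stages.  ``noise_model`` is ``"poisson"``
    (default; matches the single-pooled-library design and keeps the exact
    test's type-I calibration interpretable) or ``"negative_binomial"`` with
    ``dispersion`` theta (var = mu + mu^2/theta) for extra-Poisson spread.
    """

    n_mirnas: int = 200
    n_genes: int = 1000
    breeds: tuple[str, str] = ("LR", "LT")
    stages: tuple[str, ...] = DEFAULT_STAGES
    library_size: float = 1e6
    planted_de: list[tuple[str, tuple[str, ...], float]] = field(default_factory=list)
    noise_model: str = "poisson"
    dispersion: float = 10.0
    profile_noise_sd: float = 0.25
    utr_length: int = 500
    abundance_sigma: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise ValueError("n_mirnas and n_genes must be positive")
        if len(self.breeds) != 2:
            raise ValueError("exactly 2 breeds required")
        if len(self.stages) != 8:
            raise ValueError("exactly 8 stages required")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")
        n_emb = sum(s.endswith("E") for s in self.stages)
        n_post = sum(s.endswith("P") for s in self.stages)
        if n_emb != 4 or n_post != 4:
            raise ValueError("stages must split 4 embryonic (E) + 4 postnatal (P)")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.profile_noise_sd < 0:
            raise ValueError("profile noise sd must be non-negative")
        for mid, _stages, eff in self.planted_de:
            if not np.isfinite(eff):
                raise ValueError(f"non-finite planted effect for {mid}")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:04d}" for i in range(self.n_mirnas)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    @property
    def embryonic_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s.endswith("E"))

    @property
    def postnatal_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s.endswith("P"))


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    true_de: dict[str, tuple[frozenset[str], float]] = field(default_factory=dict)
    true_targets: list[tuple[str, str]] = field(default_factory=list)
    planted_sites: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    site_collisions: dict[str, int] = field(default_factory=dict)
    true_profile_of_gene: dict[str, int] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            true_de={**self.true_de, **other.true_de},
            true_targets=self.true_targets + other.true_targets,
            planted_sites={**self.planted_sites, **other.planted_sites},
            site_collisions={**self.site_collisions, **other.site_collisions},
            true_profile_of_gene={**self.true_profile_of_gene,
                                  **other.true_profile_of_gene},
        )


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def gen_count_libraries(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """One pooled tag-count library per (breed, stage), with planted effects.

    Library sizes are the realized column sums (every drawn tag counts as
    mapped), so TPM ratios of planted miRNAs are centred on the planted
    log2 effect up to the small compositional shift the planting itself
    induces.
    """
    rng = _rng(config, _SALT_COUNTS)
    ids = config.mirna_ids
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_mirnas)
    abundance = abundance / abundance.sum()

    labels = [f"{b}_{s}" for b in config.breeds for s in config.stages]
    mult = pd.DataFrame(1.0, index=ids, columns=labels)
    truth = GroundTruth()
    idx = {m: i for i, m in enumerate(ids)}
    for mid, stage_set, eff in config.planted_de:
        if mid not in idx:
            raise ValueError(f"planted miRNA id {mid!r} not in the simulated set")
        for stage in stage_set:
            if stage not in config.stages:
                raise ValueError(f"planted stage {stage!r} not in config.stages")
            mult.loc[mid, f"{config.breeds[0]}_{stage}"] *= 2.0 ** (eff / 2.0)
            mult.loc[mid, f"{config.breeds[1]}_{stage}"] *= 2.0 ** (-eff / 2.0)
        truth.true_de[mid] = (frozenset(stage_set), float(eff))

    # renormalize the unplanted background per library so every column's
    # expected total stays at library_size: planted miRNAs then have expected
    # TPM ratio exactly 2^effect (the background absorbs the mass shift, a
    # small compositional counter-effect as in real TPM normalization)
    w = abundance[:, None] * mult.to_numpy()
    planted_mask = mult.to_numpy() != 1.0
    planted_mass = np.where(planted_mask, w, 0.0).sum(axis=0)
    if (planted_mass >= 1.0).any():
        raise ValueError("planted effects absorb an entire library")
    background_mass = np.where(planted_mask, 0.0, w).sum(axis=0)
    scale = np.where(background_mass > 0,
                     (1.0 - planted_mass) / np.where(background_mass > 0,
                                                     background_mass, 1.0), 1.0)
    w = np.where(planted_mask, w, w * scale)
    lam = config.library_size * w
    if config.noise_model == "poisson":
        counts = rng.poisson(lam)
    else:
        theta = config.dispersion
        counts = rng.negative_binomial(theta, theta / (theta + lam))
    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=labels))
    return cm, truth


def gen_mirna_sequences(config: SimulationConfig, length: int = 22) -> dict[str, str]:
    """Random mature miRNA sequences in the RNA alphabet (5'->3')."""
    rng = _rng(config, _SALT_MIRNA_SEQ)
    alphabet = np.array(list("ACGU"))
    return {
        mid: "".join(rng.choice(alphabet, size=length))
        for mid in config.mirna_ids
    }


def gen_expression_profiles(
    config: SimulationConfig,
    profiles: list[ModelProfile],
    stage_labels: tuple[str, ...] | None = None,
    amplitude: float = 1.0,
    noise_sd: float | None = None,
    gene_ids: list[str] | None = None,
    salt: int = _SALT_FPKM,
) -> tuple[FpkmMatrix, GroundTruth]:
    """FPKM time courses drawn from integer model profiles plus noise.

    Genes cycle through the supplied templates; each gene's log2 series is
    ``amplitude * template + N(0, noise_sd)`` and FPKM = 2**series.  The
    template id of every gene is recorded in the ground truth.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    sd = config.profile_noise_sd if noise_sd is None else noise_sd
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    genes = gene_ids if gene_ids is not None else config.gene_ids
    t = len(profiles[0].values)
    if any(len(p.values) != t for p in profiles):
        raise ValueError("all templates must share one length")
    cols = stage_labels if stage_labels is not None else config.embryonic_stages
    if len(cols) != t:
        raise ValueError(f"{t}-point templates need {t} stage labels, got {len(cols)}")
    rng = _rng(config, salt)
    templates = np.array([profiles[i % len(profiles)].values for i in range(len(genes))],
                         dtype=float)
    log2 = amplitude * templates + rng.normal(0.0, sd, size=templates.shape)
    fpkm = pd.DataFrame(2.0**log2, index=genes, columns=list(cols))
    truth = GroundTruth(
        true_profile_of_gene={g: profiles[i % len(profiles)].id
                              for i, g in enumerate(genes)}
    )
    return FpkmMatrix(fpkm, pseudocount=0.0), truth


def gen_utr_sequences(
    config: SimulationConfig,
    true_targets: list[tuple[str, str]],
    mirna_sequences: dict[str, str],
) -> tuple[dict[str, str], GroundTruth]:
    """Random 3'-UTRs with seed-complement sites planted for each pair.

    Every planted (miRNA, gene) pair receives >= 1 site: the DNA reverse
    complement of the miRNA's 2-8 seed overwrites the background at a
    recorded, non-overlapping position.  Chance background occurrences of a
    planted motif are counted as collisions in the ground truth.
    """
    if config.utr_length < 7:
        raise ValueError("UTRs must be at least 7 nt to carry a seed site")
    rng = _rng(config, _SALT_UTR)
    alphabet = np.array(list("ACGT"))
    utrs = {
        g: "".join(rng.choice(alphabet, size=config.utr_length))
        for g in config.gene_ids
    }
    truth = GroundTruth(true_targets=list(true_targets))
    by_gene: dict[str, list[str]] = {}
    for mid, gene in true_targets:
        if gene not in utrs:
            raise ValueError(f"planted gene {gene!r} not in the simulated set")
        if mid not in mirna_sequences:
            raise ValueError(f"planted miRNA {mid!r} has no sequence")
        by_gene.setdefault(gene, []).append(mid)

    for gene, mids in by_gene.items():
        seq = list(utrs[gene])
        occupied: list[tuple[int, int]] = []
        for mid in mids:
            motif = seed_site_motif(extract_seed(mirna_sequences[mid]))
            for _ in range(1000):
                pos = int(rng.integers(0, config.utr_length - 7 + 1))
                if all(pos + 7 <= a or pos >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - would need a pathologically full UTR
                raise RuntimeError(f"could not place a site on {gene}")
            occupied.append((pos, pos + 7))
            seq[pos:pos + 7] = list(motif)
            truth.planted_sites.setdefault((mid, gene), []).append(pos + 1)
        utrs[gene] = "".join(seq)

    # record chance occurrences of planted motifs beyond the planted sites
    for (mid, gene), positions in truth.planted_sites.items():
        motif = seed_site_motif(extract_seed(mirna_sequences[mid]))
        seq = utrs[gene]
        found = []
        pos = seq.find(motif)
        while pos != -1:
            found.append(pos + 1)
            pos = seq.find(motif, pos + 1)
        extra = len([p for p in found if p not in positions])
        if extra:
            truth.site_collisions[gene] = truth.site_collisions.get(gene, 0) + extra
    return utrs, truth


def gen_interaction_table(
    gene_pairs: list[tuple[str, str]],
    score_range: tuple[float, float] = (0.4, 1.0),
    validated_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetric gene-gene score table for designated pairs.

    Scores are uniform in ``score_range`` (within [0, 1]); each pair is
    flagged validated or predicted.  Self-pairs are rejected and duplicate
    unordered pairs are collapsed to a single row.
    """
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("score_range must lie within [0, 1]")
    rng = np.random.default_rng([seed, _SALT_INTERACTIONS])
    seen = set()
    rows = []
    for a, b in gene_pairs:
        if a == b:
            raise ValueError(f"self-pair rejected: {a!r}")
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "node_a": key[0],
                "node_b": key[1],
                "score": float(rng.uniform(lo, hi)),
                "evidence": "validated" if rng.uniform() < validated_fraction
                            else "predicted",
            }
        )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score", "evidence"])
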