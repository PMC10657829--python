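"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover every input the analysis chain consumes:

* prescription corpora with planted herb co-occurrence blocks and
  stage-specific inclusion probabilities (so frequency tables, ordination
  and rule mining have known ground truth);
* two-sample GWAS summary statistics under the linear causal model
  b_out = theta * b_exp + alpha + noise, with a configurable fraction of
  invalid (pleiotropic) instruments, LD blocks, allele flips and palindromic
  SNPs to exercise harmonization;
* overlapping gene-target sets with exact planted region cardinalities and
  a scored interaction edge list with a planted hub.

All randomness flows from one root seed; each generator derives a child
stream by stable hashing of its name, so adding a generator never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Prescription
from .overlap import EdgeList, TargetSet

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream for ``name`` derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# prescription corpora


@dataclass(frozen=True)
class CorpusSpec:
    """Ground truth for a simulated prescription corpus.

    ``core_blocks`` plants herb sets that co-occur: each block is included
    jointly with a per-stage probability, which downstream becomes the
    expected support of that itemset.  Background herbs (never members of a
    block) enter independently at ``background_rate``.  Doses are normals
    truncated at a per-herb lower bound.
    """

    n_prescriptions_per_stage: Mapping[str, int]
    herb_universe: tuple[str, ...]
    core_blocks: tuple[tuple[frozenset[str], Mapping[str, float]], ...] = ()
    background_rate: float = 0.3
    herbs_per_prescription_range: tuple[int, int] | None = None
    dose_model: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    default_dose: tuple[float, float, float] = (15.0, 5.0, 3.0)  # mean, sd, lower
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.herb_universe:
            raise ValueError("herb universe is empty")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        for block, probs in self.core_blocks:
            if not block <= set(self.herb_universe):
                raise ValueError(f"block {sorted(block)} not within universe")
            for p in probs.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("block probabilities must be in [0, 1]")
        if self.herbs_per_prescription_range is not None:
            lo, hi = self.herbs_per_prescription_range
            if not 1 <= lo <= hi <= len(self.herb_universe):
                raise ValueError("require 1 <= lo <= hi <= |herb universe|")
            max_block = sum(
                len(b) for b, _ in self.core_blocks
            )
            if max_block > hi:
                raise ValueError(
                    "herb range infeasible: joint block size exceeds upper bound"
                )


def _draw_dose(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    # inverse-CDF sampling of the lower-truncated normal (cheaper than
    # scipy's truncnorm.rvs in the per-herb loop)
    if sd <= 0:
        return max(mean, lower)
    from scipy.special import ndtr, ndtri

    a = ndtr((lower - mean) / sd)
    u = rng.uniform(a, 1.0)
    return float(mean + sd * ndtri(u))


def simulate_corpus(spec: CorpusSpec) -> list[Prescription]:
    """Draw a corpus with the planted co-occurrence structure.

    Background herbs are drawn only from the universe outside all core
    blocks, so empirical block supports estimate the planted inclusion
    probabilities without contamination.
    """
    rng = child_rng(spec.seed, "corpus")
    block_members = set().union(*(b for b, _ in spec.core_blocks), set())
    background = [h for h in spec.herb_universe if h not in block_members]
    rng_range = spec.herbs_per_prescription_range

    out: list[Prescription] = []
    for stage, n in spec.n_prescriptions_per_stage.items():
        if n <= 0:
            raise ValueError(f"non-positive prescription count for stage {stage!r}")
        for i in range(n):
            herbs: set[str] = set()
            for block, probs in spec.core_blocks:
                if rng.random() < probs.get(stage, 0.0):
                    herbs |= block
            if background:
                mask = rng.random(len(background)) < spec.background_rate
                herbs |= {h for h, m in zip(background, mask) if m}
            if rng_range is not None:
                lo, hi = rng_range
                extras = [h for h in background if h not in herbs]
                rng.shuffle(extras)
                while len(herbs) < lo and extras:
                    herbs.add(extras.pop())
                if len(herbs) > hi:
                    removable = [h for h in sorted(herbs) if h not in block_members]
                    rng.shuffle(removable)
                    while len(herbs) > hi and removable:
                        herbs.discard(removable.pop())
            if not herbs:  # a prescription must contain something
                herbs.add(background[int(rng.integers(len(background)))]
                          if background else spec.herb_universe[0])
            herb_doses = []
            for h in sorted(herbs):
                mean, sd, lower = spec.dose_model.get(h, spec.default_dose)
                herb_doses.append((h, _draw_dose(rng, mean, sd, lower)))
            out.append(Prescription(f"{stage}_{i:04d}", stage, tuple(herb_doses)))
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics


@dataclass(frozen=True)
class GwasSimSpec:
    """Two-sample summary-statistics simulation under
    b_out = theta * b_exp + alpha + noise.

    Valid instruments have alpha = 0; a fraction ``invalid_fraction`` draw
    alpha ~ N(pleiotropy_mean, pleiotropy_sd^2) (directional when the mean
    is nonzero, balanced otherwise).  Standard errors follow the standard
    per-allele form se = 1 / sqrt(2 * maf * (1 - maf) * n).  ``noise_scale``
    rescales the sampling noise on the observed betas (0 gives the exact
    noise-free limit).  A fraction of outcome records has effect/other
    alleles swapped, and some SNPs are palindromic, to exercise every
    harmonization branch.
    """

    n_snps: int = 30
    theta: float = 0.0
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_beta_dist: tuple[float, float] = (0.15, 0.05)
    n_exposure: int = 18_340
    n_outcome: int = 377_277
    ld_blocks: tuple[tuple[int, float], ...] = ()
    maf_range: tuple[float, float] = (0.05, 0.5)
    allele_flip_fraction: float = 0.2
    palindromic_fraction: float = 0.1
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")


def simulate_gwas(
    spec: GwasSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[frozenset[str], float]]:
    """Exposure table, outcome table, and a pairwise r^2 lookup.

    SNPs belonging to an LD block share a chromosome and sit 10 kb apart
    with the block's r^2 between every pair; SNPs outside blocks are placed
    1 Mb apart (independent for any 500 kb clumping window).
    """
    rng = child_rng(spec.seed, "gwas")
    m = spec.n_snps
    maf = rng.uniform(*spec.maf_range, size=m)
    se_exp = 1.0 / np.sqrt(2 * maf * (1 - maf) * spec.n_exposure)
    se_out = 1.0 / np.sqrt(2 * maf * (1 - maf) * spec.n_outcome)

    mu, sd = spec.exposure_beta_dist
    beta_exp_true = rng.normal(mu, sd, size=m)

    n_invalid = int(round(spec.invalid_fraction * m))
    alpha = np.zeros(m)
    if n_invalid:
        invalid_idx = rng.choice(m, size=n_invalid, replace=False)
        alpha[invalid_idx] = rng.normal(
            spec.pleiotropy_mean, spec.pleiotropy_sd, size=n_invalid
        )
    beta_out_true = spec.theta * beta_exp_true + alpha

    ns = spec.noise_scale
    beta_exp_hat = beta_exp_true + ns * rng.normal(0.0, se_exp)
    beta_out_hat = beta_out_true + ns * rng.normal(0.0, se_out)

    # genomic placement: LD blocks first, then independent SNPs
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    ld: dict[frozenset[str], float] = {}
    rsids = np.array([f"rs{100000 + j}" for j in range(m)])
    j = 0
    c = 1
    for size, r2 in spec.ld_blocks:
        members = list(range(j, min(j + size, m)))
        for k, idx in enumerate(members):
            chrom[idx] = c
            pos[idx] = 1_000_000 + 10_000 * k
        for a in members:
            for b in members:
                if a < b:
                    ld[frozenset((rsids[a], rsids[b]))] = r2
        j += size
        c += 1
    for k in range(j, m):
        chrom[k] = c + (k - j) % 22
        pos[k] = 1_000_000 + 1_000_000 * ((k - j) // 22 + 1)

    # alleles
    pal = rng.random(m) < spec.palindromic_fraction
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    ea = np.where(pal,
                  [ _PALINDROMIC_PAIRS[i][0] for i in pal_idx ],
                  [ _NONPALINDROMIC_PAIRS[i][0] for i in pair_idx ])
    oa = np.where(pal,
                  [ _PALINDROMIC_PAIRS[i][1] for i in pal_idx ],
                  [ _NONPALINDROMIC_PAIRS[i][1] for i in pair_idx ])

    def table(beta, se, n):
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        from scipy.stats import norm

        p = np.clip(2 * norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
        return pd.DataFrame(
            {
                "rsid": rsids, "chrom": chrom, "pos": pos,
                "effect_allele": ea, "other_allele": oa,
                "eaf": maf.copy(), "beta": beta, "se": se, "p": p,
                "n": np.full(m, n),
            }
        )

    exposure = table(beta_exp_hat, se_exp, spec.n_exposure)
    outcome = table(beta_out_hat, se_out, spec.n_outcome)

    flip = rng.random(m) < spec.allele_flip_fraction
    outcome.loc[flip, ["effect_allele", "other_allele"]] = outcome.loc[
        flip, ["other_allele", "effect_allele"]
    ].to_numpy()
    outcome.loc[flip, "beta"] = -outcome.loc[flip, "beta"]
    outcome.loc[flip, "eaf"] = 1.0 - outcome.loc[flip, "eaf"]
    return exposure, outcome, ld


# ---------------------------------------------------------------------------
# target sets and edge lists


def simulate_target_sets(
    n_universe: int,
    region_sizes: Mapping[tuple[str, ...], int],
    planted_hub: str | None = None,
    seed: int = 0,
    labels: Sequence[str] = ("herb", "microbe_metabolite", "disease"),
) -> tuple[list[TargetSet], EdgeList]:
    """Three gene sets with exact exclusive-region cardinalities, plus a
    scored edge list whose strictly-highest-degree node is the planted hub.

    ``region_sizes`` keys are sorted label tuples (singletons through the
    full triple) giving exclusive region sizes; unspecified regions are
    empty.  The hub (default: the first core gene) is wired to every other
    core gene at score 0.9; remaining core genes form a chain at score 0.5
    plus sub-cutoff edges at 0.2.
    """
    sizes = {tuple(sorted(k)): v for k, v in region_sizes.items()}
    for k in sizes:
        if not set(k) <= set(labels):
            raise ValueError(f"unknown labels in region {k}")
    total = sum(sizes.values())
    if total > n_universe:
        raise ValueError(
            f"region sizes total {total} exceeds universe {n_universe}"
        )
    rng = child_rng(seed, "targets")
    genes = [f"G{j:05d}" for j in range(n_universe)]
    rng.shuffle(genes)
    cursor = 0
    members: dict[str, set[str]] = {l: set() for l in labels}
    core: list[str] = []
    for region, size in sorted(sizes.items()):
        chunk = genes[cursor : cursor + size]
        cursor += size
        for l in region:
            members[l].update(chunk)
        if set(region) == set(labels):
            core = sorted(chunk)
    sets = [TargetSet(l, frozenset(members[l])) for l in labels if members[l]]

    edges: list[tuple[str, str, float]] = []
    if core:
        hub = planted_hub if planted_hub is not None else core[0]
        if hub not in core:
            raise ValueError(f"planted hub {hub!r} is not a core gene")
        spokes = [g for g in core if g != hub]
        edges += [(hub, g, 0.9) for g in spokes]
        edges += [(spokes[i], spokes[i + 1], 0.5) for i in range(len(spokes) - 1)]
        # sub-cutoff noise edges, invisible at the default 0.4 threshold
        edges += [(spokes[i], spokes[(i + 2) % len(spokes)], 0.2)
                  for i in range(0, max(len(spokes) - 2, 0), 3)]
    return sets, EdgeList.from_tuples(edges)
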