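"""Synthetic cohort generator.

Emulates the statistical structure of a crypt-resolved whole-genome study
of normal small-intestine epithelium: monoclonal crypts whose somatic
mutations sit at VAF 0.5, shared ancestral branches created by crypt
fission, per-year mutation accrual from a mixture of mutational
signatures, episodic APOBEC (SBS2/SBS13) bursts on a subset of branches
with embedded kataegis clusters, heterozygous germline variants shared by
all crypts of a patient, and systematic low-VAF artifacts shared across
samples — all observed through Poisson-distributed depth and binomial
read sampling.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``SimulationConfig.seed``, so outputs are bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import default_catalog
from .containers import REGIONS, FissionNode, FissionTree, VariantCounts
from .trinuc import channel_alt, channel_context, context_positions, revcomp

_MIN_GENOME = 10_000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Rates and depth default to the conditions of the study this package
    models: mean coverage 25x and SBS accrual of 51/50/42 mutations per
    year in duodenum/jejunum/ileum.
    """

    seed: int = 0
    genome_length: int = 200_000
    n_patients: int = 5
    crypts_per_patient: int = 8
    mean_depth: float = 25.0
    sbs_rate_per_year: dict = field(
        default_factory=lambda: {"duodenum": 51.0, "jejunum": 50.0, "ileum": 42.0}
    )
    id_rate_per_year: float = 3.0
    signature_mix: dict = field(
        default_factory=lambda: {"SBS1": 0.33, "SBS5": 0.55, "SBS18": 0.12}
    )
    apobec_episode_prob: float = 0.15
    apobec_burst_size: int = 300
    kataegis_per_burst: int = 1
    kataegis_cluster_size: int = 6
    kataegis_span: int = 2_000
    germline_het_count: int = 1_000
    artifact_count: int = 150
    artifact_vaf: float = 0.03
    artifact_rho: float = 0.02
    fission_age_range: tuple = (0.0, 10.0)
    age_range: tuple = (30.0, 80.0)
    celiac_fraction: float = 0.0
    celiac_sbs1_extra_per_year: float = 4.8
    male_sex_chrom: bool = False

    def __post_init__(self) -> None:
        if self.genome_length < _MIN_GENOME:
            raise ValueError(f"genome_length must be >= {_MIN_GENOME}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        total = sum(self.signature_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature_mix weights sum to {total}, expected 1")
        for name, p in [
            ("apobec_episode_prob", self.apobec_episode_prob),
            ("artifact_vaf", self.artifact_vaf),
            ("celiac_fraction", self.celiac_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth behind one synthetic cohort.

    ``mutations`` has one row per distinct simulated variant with its
    originating patient/branch, generating signature, kataegis cluster id
    ('' if unclustered) and label in {somatic, germline, artifact}.
    """

    mutations: pd.DataFrame
    trees: dict[str, FissionTree]
    rates: dict[str, float]


@dataclass
class CohortBundle:
    truth: TruthSet
    counts: VariantCounts
    metrics: pd.DataFrame
    metadata: pd.DataFrame
    reference: dict[str, str]


def generate_reference(genome_length: int, seed: int) -> str:
    """Uniform-random reference sequence over {A,C,G,T}."""
    if genome_length < _MIN_GENOME:
        raise ValueError(f"genome_length must be >= {_MIN_GENOME}")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, genome_length)])


def _fission_tree(
    rng: np.random.Generator,
    crypts: list[str],
    sampling_age: float,
    fission_age_range: tuple,
) -> FissionTree:
    """Random binary fission history: at each of k-1 sorted uniform fission
    ages a uniformly chosen extant lineage splits in two."""
    lo, hi = fission_age_range
    hi = min(hi, sampling_age)
    lo = min(lo, hi)
    k = len(crypts)
    times = np.sort(rng.uniform(lo, hi, size=k - 1)) if k > 1 else np.array([])
    nodes = {0: FissionNode(0, None, 0.0, sampling_age)}
    active = [0]
    next_id = 1
    for t in times:
        split = active.pop(int(rng.integers(len(active))))
        nodes[split].end_age = float(t)
        for _ in range(2):
            nodes[next_id] = FissionNode(next_id, split, float(t), sampling_age)
            nodes[split].children.append(next_id)
            active.append(next_id)
            next_id += 1
    order = rng.permutation(len(crypts))
    for leaf_id, crypt_idx in zip(active, order):
        nodes[leaf_id].crypts = [crypts[int(crypt_idx)]]
    # fill clades bottom-up
    for nid in sorted(nodes, reverse=True):
        node = nodes[nid]
        if node.children:
            node.crypts = sorted(
                c for child in node.children for c in nodes[child].crypts
            )
    return FissionTree(nodes, 0, sampling_age)


class _PositionPool:
    """Context-matched position sampler with collision avoidance."""

    def __init__(self, chrom: str, seq: str, rng: np.random.Generator):
        self.chrom = chrom
        self.seq = seq.upper()
        self.rng = rng
        self.index = context_positions(seq)
        self.used: set[int] = set()
        self.all_positions = np.arange(2, len(seq), dtype=np.int64)

    def draw_for_context(self, context: str, lo: int | None = None, hi: int | None = None) -> int:
        """A fresh position whose (strand-normalized) trinucleotide is
        ``context``, optionally restricted to [lo, hi]; rejection sampling
        capped at 10^6 draws."""
        pool = self.index.get(context)
        if pool is None or len(pool) == 0:
            raise RuntimeError(f"no positions with context {context} in reference")
        if lo is not None:
            pool = pool[(pool >= lo) & (pool <= hi)]
            if len(pool) == 0:
                raise RuntimeError(f"no {context} positions in window [{lo}, {hi}]")
        for _ in range(1_000_000):
            pos = int(pool[self.rng.integers(len(pool))])
            if pos not in self.used:
                self.used.add(pos)
                return pos
        raise RuntimeError("position sampling exhausted; genome too small for load")

    def draw_any(self) -> int:
        for _ in range(1_000_000):
            pos = int(self.all_positions[self.rng.integers(len(self.all_positions))])
            if pos not in self.used:
                self.used.add(pos)
                return pos
        raise RuntimeError("position sampling exhausted")

    def forward_alleles(self, pos: int, channel: str) -> tuple[str, str]:
        """(ref, alt) on the forward strand for a channel placed at pos."""
        ref = self.seq[pos - 1]
        alt = channel_alt(channel)
        if ref in "AG":  # context matched on the reverse strand
            alt = revcomp(alt)
        return ref, alt


def _draw_channels(rng, catalog, signature: str, n: int) -> list[str]:
    probs = catalog[signature].values
    idx = rng.choice(len(probs), size=n, p=probs)
    return [catalog.index[i] for i in idx]


def generate_cohort(
    config: SimulationConfig,
    reference: dict[str, str] | str | None = None,
    catalog: pd.DataFrame | None = None,
) -> CohortBundle:
    """Simulate a full cohort: truth, observed read counts, read metrics
    and sample metadata."""
    rng = np.random.default_rng(config.seed)
    if catalog is None:
        catalog = default_catalog()
    for name in config.signature_mix:
        if name not in catalog.columns:
            raise ValueError(f"signature {name!r} absent from catalog")
    for name in ("SBS2", "SBS13"):
        if config.apobec_episode_prob > 0 and name not in catalog.columns:
            raise ValueError(f"APOBEC bursts need {name} in the catalog")

    if reference is None:
        reference = {"chr1": generate_reference(config.genome_length, config.seed)}
    elif isinstance(reference, str):
        reference = {"chr1": reference}
    if config.male_sex_chrom and "chrX" not in reference:
        reference = dict(reference)
        reference["chrX"] = generate_reference(
            max(_MIN_GENOME, config.genome_length // 5), config.seed + 1
        )
    pools = {c: _PositionPool(c, s, rng) for c, s in reference.items()}
    autosome = pools["chr1"]

    mix_names = list(config.signature_mix)
    mix_w = np.array([config.signature_mix[s] for s in mix_names])

    meta_rows, truth_rows, trees = [], [], {}
    # carriers[variant_id] = (patient or None, set of carrier samples, vaf)
    carriers: dict[str, tuple] = {}
    all_samples: list[str] = []
    vid = 0

    def new_vid(prefix: str) -> str:
        nonlocal vid
        vid += 1
        return f"{prefix}{vid:06d}"

    for pi in range(config.n_patients):
        # site uniqueness is enforced within a patient; different patients
        # may (rarely) mutate the same site, as in real cohorts
        for pool in pools.values():
            pool.used.clear()
        patient = f"P{pi + 1:02d}"
        region = REGIONS[pi % len(REGIONS)]
        age = float(rng.uniform(*config.age_range))
        celiac = int(rng.random() < config.celiac_fraction)
        sex = "M" if (config.male_sex_chrom and pi % 2 == 0) else "F"
        crypts = [f"{patient}_crypt{j + 1:02d}" for j in range(config.crypts_per_patient)]
        all_samples.extend(crypts)
        for s in crypts:
            meta_rows.append(
                dict(sample_id=s, patient=patient, age_years=age, region=region,
                     celiac=celiac, sex=sex, mean_coverage=config.mean_depth)
            )
        tree = _fission_tree(rng, crypts, age, config.fission_age_range)
        trees[patient] = tree

        sbs_rate = config.sbs_rate_per_year[region]
        sbs1_extra = config.celiac_sbs1_extra_per_year if celiac else 0.0

        for node in tree.branches():
            branch_samples = set(node.crypts)
            years = node.duration
            # background SBS accrual from the signature mixture
            n_sbs = rng.poisson(sbs_rate * years)
            extra1 = rng.poisson(sbs1_extra * years) if sbs1_extra else 0
            sig_draws = list(np.array(mix_names)[rng.choice(len(mix_w), n_sbs, p=mix_w)])
            sig_draws += ["SBS1"] * extra1
            for sig in sig_draws:
                channel = _draw_channels(rng, catalog, sig, 1)[0]
                pos = autosome.draw_for_context(channel_context(channel))
                ref, alt = autosome.forward_alleles(pos, channel)
                v = new_vid("s")
                truth_rows.append(
                    dict(variant_id=v, chrom="chr1", pos=pos, ref=ref, alt=alt,
                         variant_class="SBS", context=channel_context(channel),
                         patient=patient, branch_id=node.node_id, signature=sig,
                         kataegis_id="", label="somatic")
                )
                carriers[v] = (patient, branch_samples, 0.5)
            # indels: single-base insertions/deletions, no signature structure
            for _ in range(rng.poisson(config.id_rate_per_year * years)):
                pos = autosome.draw_any()
                base = autosome.seq[pos - 1]
                if rng.random() < 0.5:
                    ref, alt = base, base + "ACGT"[rng.integers(4)]
                else:
                    ref, alt = base + autosome.seq[pos], base
                v = new_vid("i")
                truth_rows.append(
                    dict(variant_id=v, chrom="chr1", pos=pos, ref=ref, alt=alt,
                         variant_class="ID", context="", patient=patient,
                         branch_id=node.node_id, signature="ID", kataegis_id="",
                         label="somatic")
                )
                carriers[v] = (patient, branch_samples, 0.5)
            # episodic APOBEC burst
            if config.apobec_episode_prob and rng.random() < config.apobec_episode_prob:
                _apobec_burst(config, rng, catalog, autosome, patient, node,
                              branch_samples, truth_rows, carriers, new_vid)

        # germline heterozygous variants
        for g in range(config.germline_het_count):
            on_x = sex == "M" and config.male_sex_chrom and g % 10 == 0
            pool = pools["chrX"] if on_x else autosome
            pos = pool.draw_any()
            ref = pool.seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
            v = new_vid("g")
            truth_rows.append(
                dict(variant_id=v, chrom=pool.chrom, pos=pos, ref=ref, alt=alt,
                     variant_class="SBS", context="", patient=patient, branch_id=-1,
                     signature="germline", kataegis_id="", label="germline")
            )
            carriers[v] = (patient, set(crypts), 0.95 if on_x else 0.5)

    # systematic artifacts: same low-VAF sites in every sample of the cohort
    for _ in range(config.artifact_count):
        pos = autosome.draw_any()
        ref = autosome.seq[pos - 1]
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        v = new_vid("a")
        truth_rows.append(
            dict(variant_id=v, chrom="chr1", pos=pos, ref=ref, alt=alt,
                 variant_class="SBS", context="", patient="", branch_id=-1,
                 signature="artifact", kataegis_id="", label="artifact")
        )
        carriers[v] = (None, set(), config.artifact_vaf)

    truth_df = pd.DataFrame(truth_rows)
    metadata = pd.DataFrame(meta_rows)
    counts = _observe(config, rng, truth_df, carriers, all_samples)
    metrics = _read_metrics(rng, truth_df, counts)
    return CohortBundle(TruthSet(truth_df, trees, dict(config.sbs_rate_per_year)),
                        counts, metrics, metadata, reference)


def _apobec_burst(config, rng, catalog, pool, patient, node, branch_samples,
                  truth_rows, carriers, new_vid) -> None:
    n_clustered = config.kataegis_per_burst * config.kataegis_cluster_size
    n_diffuse = max(0, config.apobec_burst_size - n_clustered)
    placements: list[tuple[str, str, int | None, int | None]] = []  # sig, kat_id, lo, hi
    for _ in range(n_diffuse):
        sig = "SBS2" if rng.random() < 0.5 else "SBS13"
        placements.append((sig, "", None, None))
    for c in range(config.kataegis_per_burst):
        kat_id = f"{patient}_b{node.node_id}_k{c}"
        lo = int(rng.integers(2, len(pool.seq) - config.kataegis_span - 2))
        hi = lo + config.kataegis_span
        for _ in range(config.kataegis_cluster_size):
            sig = "SBS2" if rng.random() < 0.5 else "SBS13"
            placements.append((sig, kat_id, lo, hi))
    for sig, kat_id, lo, hi in placements:
        channel = _draw_channels(rng, catalog, sig, 1)[0]
        try:
            pos = pool.draw_for_context(channel_context(channel), lo, hi)
        except RuntimeError:
            if kat_id == "":
                raise
            # fall back to any TC* context available in the window
            for ctx in ("TCA", "TCT", "TCC", "TCG"):
                try:
                    pos = pool.draw_for_context(ctx, lo, hi)
                    break
                except RuntimeError:
                    continue
            else:  # pragma: no cover - window devoid of TpC sites
                continue
        ref, alt = pool.forward_alleles(pos, channel)
        v = new_vid("s")
        truth_rows.append(
            dict(variant_id=v, chrom=pool.chrom, pos=pos, ref=ref, alt=alt,
                 variant_class="SBS", context=channel_context(channel),
                 patient=patient, branch_id=node.node_id, signature=sig,
                 kataegis_id=kat_id, label="somatic")
        )
        carriers[v] = (patient, branch_samples, 0.5)


def _observe(config, rng, truth_df, carriers, samples) -> VariantCounts:
    n_var, n_samp = len(truth_df), len(samples)
    sample_pos = {s: j for j, s in enumerate(samples)}
    depth = rng.poisson(config.mean_depth, size=(n_var, n_samp))
    alt = np.zeros_like(depth)
    a = config.artifact_vaf * (1 - config.artifact_rho) / config.artifact_rho
    b = (1 - config.artifact_vaf) * (1 - config.artifact_rho) / config.artifact_rho
    for i, v in enumerate(truth_df["variant_id"]):
        patient, carrier_set, vaf = carriers[v]
        if patient is None:  # artifact: beta-binomial across every sample
            p = rng.beta(a, b, size=n_samp)
            alt[i] = rng.binomial(depth[i], p)
        else:
            cols = [sample_pos[s] for s in carrier_set]
            alt[i, cols] = rng.binomial(depth[i, cols], vaf)
    ids = pd.Index(truth_df["variant_id"], name="variant_id")
    info = truth_df[["variant_id", "chrom", "pos", "ref", "alt", "variant_class"]].copy()
    return VariantCounts(
        info,
        pd.DataFrame(alt, index=ids, columns=samples),
        pd.DataFrame(depth, index=ids, columns=samples),
    )


def _read_metrics(rng, truth_df, counts) -> pd.DataFrame:
    """Per-variant read metrics; all variants here are well-mapped, so the
    read-metric stage should pass them (mapping artifacts are exercised by
    hand-built tables in tests)."""
    n = len(truth_df)
    is_id = (truth_df["variant_class"] == "ID").values
    # supporting depth is the depth where the variant is actually seen
    alt = counts.alt.values
    depth = counts.depth.values
    seen = alt > 0
    with np.errstate(invalid="ignore"):
        support_depth = np.where(
            seen.any(axis=1),
            (depth * seen).sum(axis=1) / np.maximum(seen.sum(axis=1), 1),
            depth.mean(axis=1),
        )
    return pd.DataFrame(
        dict(
            variant_id=truth_df["variant_id"].values,
            median_alignment_score=np.clip(rng.normal(200, 15, n), 0, 254).round(1),
            clipped_fraction=np.round(rng.beta(1, 30, n), 4),
            pindel_quality=np.where(is_id, np.clip(rng.normal(450, 60, n), 0, None), np.nan).round(1),
            min_supporting_depth=np.where(is_id, np.round(support_depth, 1), np.nan),
        )
    )


def male_config(config: SimulationConfig) -> SimulationConfig:
    """Convenience: same conditions with the male X germline mode on."""
    return replace(config, male_sex_chrom=True)
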