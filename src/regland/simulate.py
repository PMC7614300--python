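"""Synthetic-data generator with planted ground truth.

Emulates every input of the pipeline on a toy contig: negative-binomial
fragment counts with planted accessibility patterns over a neural-tube
differentiation design (an NMP-like origin state plus four progenitor
cell types, one of which — p3 — carries a private accessibility
program), footprint score tables whose pioneer archetype tracks the
unique cell type and couples to a planted driver TF's RNA, ChIP peak
sets enriched in a chosen pattern, and multi-channel section images
with planted p3/V3/other nuclei and tdTomato labels.

The generator is the ground truth against which every downstream module
is tested; its defaults are the study conditions, not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regland.counts import CountMatrix, SampleTable
from regland.errors import ParameterError
from regland.footprint import PWM, ArchetypeMap
from regland.imaging import ImageStack
from regland.peaks import PeakSet

Condition = tuple[str, int, int]  # (cell_type, day, sag_nM)


def default_cell_types() -> list[tuple[str, str]]:
    return [("p0-1", "shared"), ("p2", "shared"),
            ("pMN", "shared"), ("p3", "unique")]


def default_conditions() -> list[Condition]:
    """An NMP origin at days 3-4 plus four progenitors at days 4-6,
    each progenitor generated at its characteristic SAG dose."""
    sag = {"p0-1": 0, "p2": 10, "pMN": 100, "p3": 500}
    conds: list[Condition] = [("NMP", 3, 0), ("NMP", 4, 0)]
    for ct in ("p0-1", "p2", "pMN", "p3"):
        for day in (4, 5, 6):
            conds.append((ct, day, sag[ct]))
    return conds


def condition_label(cond: Condition) -> str:
    ct, day, sag = cond
    return f"{ct}.d{day}.sag{sag}"


@dataclass
class ImageSimConfig:
    """Parameters of the synthetic section images."""

    n_sections: int = 8
    n_nuclei: int = 40
    radius_px: int = 6
    shape: tuple[int, int] = (220, 220)
    noise_sd: float = 5.0
    background: float = 10.0
    channel_means: dict = field(default_factory=lambda: {
        "p3": {"DAPI": 200.0, "SOX2": 180.0, "NKX2.2": 180.0},
        "V3": {"DAPI": 200.0, "SOX2": 20.0, "NKX2.2": 180.0},
        "other": {"DAPI": 200.0, "SOX2": 180.0, "NKX2.2": 20.0},
    })
    tdtomato_on: float = 160.0
    tdtomato_off: float = 20.0
    class_probs: dict = field(default_factory=lambda: {
        "p3": 0.4, "V3": 0.3, "other": 0.3})
    tdtomato_prob: dict = field(default_factory=lambda: {
        "p3": 0.5, "V3": 0.5, "other": 0.1})
    n_far_nkx: int = 0   # planted far NKX2.2+ background-binding cells
    max_attempts: int = 50_000


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment."""

    seed: int = 0
    n_elements: int = 1800
    n_planted_patterns: int = 9
    cell_types: list = field(default_factory=default_cell_types)
    conditions: list = field(default_factory=default_conditions)
    n_replicates: int = 3
    frac_constitutive: float = 0.3
    baseline_mean: float = 50.0
    effect_log2fc: float = 3.0
    nb_dispersion: float = 0.2
    n_motifs: int = 60
    n_archetypes: int = 10
    n_decoys: int = 5
    driver_correlation: float = 0.9
    motif_noise_sd: float = 0.2
    frip_target: float = 0.65
    image: ImageSimConfig = field(default_factory=ImageSimConfig)

    def __post_init__(self) -> None:
        if self.n_planted_patterns < 2:
            raise ParameterError("n_planted_patterns must be >= 2")
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if not 0.0 <= self.frac_constitutive < 1.0:
            raise ParameterError("frac_constitutive must be in [0, 1)")
        if self.baseline_mean <= 0:
            raise ParameterError("baseline_mean must be > 0")
        if not -1.0 <= self.driver_correlation <= 1.0:
            raise ParameterError("driver_correlation must be in [-1, 1]")
        for cls, means in self.image.channel_means.items():
            if any(v < 0 for v in means.values()):
                raise ParameterError(
                    f"image.channel_means[{cls!r}] must be >= 0")

    @property
    def unique_cell_type(self) -> str:
        uniq = [ct for ct, regime in self.cell_types if regime == "unique"]
        if len(uniq) != 1:
            raise ParameterError("cell_types must contain exactly one "
                                 "'unique'-regime cell type")
        return uniq[0]


@dataclass
class GroundTruth:
    """Planted truth recorded by the generator."""

    element_pattern: pd.Series | None = None      # element_id -> pattern id
    pattern_profile: pd.DataFrame | None = None   # pattern x condition (bool)
    pattern_names: dict = field(default_factory=dict)
    library_factors: pd.Series | None = None
    driver_tf: dict = field(default_factory=dict)  # archetype -> gene
    nucleus_truth: list = field(default_factory=list)  # per-section tables


def planted_patterns(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Build n_planted_patterns distinct open/closed condition profiles.

    Candidates, in priority order: origin program (decommissioned after
    the origin state), pan-neural, unique-cell-type-specific, unique
    late, the program shared by all non-unique progenitors, late/early
    phases and single-day waves. Patterns that would be empty,
    all-open, or duplicates are skipped.
    """
    conds = list(config.conditions)
    labels = [condition_label(c) for c in conds]
    cts = {ct for ct, _, _ in conds}
    progenitors = [ct for ct, _ in config.cell_types]
    origin_cts = sorted(cts - set(progenitors))
    uniq = config.unique_cell_type
    days = sorted({d for _, d, _ in conds})

    def mask(fn):
        return np.array([bool(fn(ct, d)) for ct, d, _ in conds])

    late_days = set(days[-2:])
    mid_days = set(days[1:3])
    # candidate profiles are chosen pairwise-dissimilar (binary Pearson
    # correlation <= ~0.6) so that correlation-distance merging can tell
    # them apart; highly collinear programs would not be recoverable by
    # any clustering of dynamics
    candidates: list[tuple[str, np.ndarray]] = [
        ("origin", mask(lambda ct, d: ct in origin_cts)),
        ("pan-neural", mask(lambda ct, d: ct not in origin_cts)),
        (f"{uniq}-specific", mask(lambda ct, d: ct == uniq)),
        ("shared-progenitor", mask(lambda ct, d: ct not in origin_cts
                                   and ct != uniq)),
        ("late", mask(lambda ct, d: d in late_days)),
        ("transient", mask(lambda ct, d: d in mid_days)),
    ]
    for d in days[1:]:
        candidates.append((f"day{d}-wave", mask(lambda ct, dd, d=d: dd == d)))

    profiles: list[np.ndarray] = []
    names: dict[int, str] = {}
    seen: set[tuple] = set()
    for name, m in candidates:
        key = tuple(m)
        if not m.any() or m.all() or key in seen:
            continue
        seen.add(key)
        profiles.append(m)
        names[len(profiles)] = name
        if len(profiles) == config.n_planted_patterns:
            break
    if len(profiles) < config.n_planted_patterns:
        raise ParameterError(
            f"conditions support only {len(profiles)} distinct patterns; "
            f"n_planted_patterns={config.n_planted_patterns} is too large"
        )
    profile = pd.DataFrame(np.array(profiles),
                           index=pd.RangeIndex(1, len(profiles) + 1,
                                               name="pattern"),
                           columns=labels)
    return profile, names


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion < 1e-10:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mu))


def simulate_accessibility(config: SimulationConfig,
                           ) -> tuple[PeakSet, CountMatrix, SampleTable,
                                      GroundTruth]:
    """Peaks, counts and metadata with planted accessibility patterns.

    Element means are baseline_mean * 2^(effect_log2fc * open) scaled by
    per-sample library factors (log-uniform in [0.5, 2]); counts are
    NB(mu, alpha) with variance mu + alpha*mu^2.
    """
    rng = np.random.default_rng(config.seed)
    profile, names = planted_patterns(config)
    conds = list(config.conditions)
    labels = list(profile.columns)

    sample_rows = []
    sample_cond_idx = []
    for ci, (ct, day, sag) in enumerate(conds):
        for rep in range(1, config.n_replicates + 1):
            sample_rows.append((f"{condition_label((ct, day, sag))}.r{rep}",
                                ct, sag, day, rep))
            sample_cond_idx.append(ci)
    samples = SampleTable(pd.DataFrame(
        sample_rows, columns=["sample_id", "cell_type", "sag_nM", "day",
                              "replicate"]))
    n_samples = len(sample_rows)

    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))
    element_ids = [f"el_{i + 1}" for i in range(config.n_elements)]
    # pattern 0 = constitutive background (open everywhere, not dynamic);
    # patterns 1..P are the planted dynamic programs
    n_const = int(round(config.frac_constitutive * config.n_elements))
    pattern = np.concatenate([
        np.zeros(n_const, dtype=int),
        np.resize(np.arange(1, config.n_planted_patterns + 1),
                  config.n_elements - n_const),
    ])
    rng.shuffle(pattern)

    profile_with_const = np.vstack([
        np.ones(len(profile.columns), dtype=bool), profile.to_numpy()])
    open_mat = profile_with_const[pattern][:, sample_cond_idx]
    mu = (config.baseline_mean
          * 2.0 ** (config.effect_log2fc * open_mat)
          * lib[None, :])
    values = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(values, index=pd.Index(element_ids),
                             columns=samples.sample_ids)
    library_total = pd.Series(
        np.ceil(counts_df.sum(axis=0) / config.frip_target).astype(np.int64),
        index=samples.sample_ids)
    counts = CountMatrix(counts_df, library_total=library_total)

    width, spacing = 500, 1000
    peak_df = pd.DataFrame({
        "chrom": "chrS",
        "start": np.arange(config.n_elements) * spacing + 200,
        "end": np.arange(config.n_elements) * spacing + 200 + width,
        "id": element_ids,
    })
    open_any = open_mat.astype(bool)
    qv = np.where(open_any,
                  10.0 ** -rng.uniform(6.0, 12.0, size=open_any.shape),
                  rng.uniform(0.2, 0.8, size=open_any.shape))
    qval = pd.DataFrame(qv, index=pd.Index(element_ids),
                        columns=samples.sample_ids)
    peaks = PeakSet(peak_df, qval=qval)

    truth = GroundTruth(
        element_pattern=pd.Series(pattern, index=pd.Index(element_ids),
                                  name="pattern"),
        pattern_profile=profile,
        pattern_names=names,
        library_factors=pd.Series(lib, index=samples.sample_ids,
                                  name="library_factor"),
    )
    return peaks, counts, samples, truth


def simulate_two_group(seed: int, n_elements: int = 2000,
                       frac_differential: float = 0.1,
                       effect_log2fc: float = 3.0,
                       nb_dispersion: float = 0.2,
                       baseline_mean: float = 400.0,
                       n_replicates: int = 3,
                       ) -> tuple[CountMatrix, list[str], list[str],
                                  pd.Series]:
    """A minimal two-group NB experiment for power/calibration studies.

    A `frac_differential` share of elements carries |log2FC| =
    `effect_log2fc` in group B (half up, half down); the rest are null.
    Library factors are log-uniform in [0.5, 2] as in the main
    generator. The default baseline of 400 fragments models
    well-covered accessible elements: even an 8-fold-down element then
    stays above a baseMean floor of 100, so power studies measure the
    test, not the coverage filter. Returns (counts, group_A ids,
    group_B ids, per-element planted log2FC).
    """
    if not 0.0 <= frac_differential <= 1.0:
        raise ParameterError("frac_differential must be in [0, 1]")
    if nb_dispersion <= 0:
        raise ParameterError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    n_diff = int(round(frac_differential * n_elements))
    lfc = np.zeros(n_elements)
    lfc[:n_diff // 2] = effect_log2fc
    lfc[n_diff // 2:n_diff] = -effect_log2fc
    rng.shuffle(lfc)
    group_a = [f"A_r{i + 1}" for i in range(n_replicates)]
    group_b = [f"B_r{i + 1}" for i in range(n_replicates)]
    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0),
                             size=2 * n_replicates))
    mu = np.empty((n_elements, 2 * n_replicates))
    mu[:, :n_replicates] = baseline_mean
    mu[:, n_replicates:] = baseline_mean * 2.0 ** lfc[:, None]
    mu *= lib[None, :]
    values = _nb_draw(rng, mu, nb_dispersion)
    ids = pd.Index([f"el_{i + 1}" for i in range(n_elements)])
    counts = CountMatrix(pd.DataFrame(values, index=ids,
                                      columns=group_a + group_b))
    return counts, group_a, group_b, pd.Series(lfc, index=ids,
                                               name="planted_log2fc")


def _seed_pwm(rng: np.random.Generator, length: int = 8) -> np.ndarray:
    mat = np.full((4, length), 0.07)
    consensus = rng.integers(0, 4, size=length)
    mat[consensus, np.arange(length)] = 0.79
    return mat


def _shift(mat: np.ndarray, by: int) -> np.ndarray:
    pad = np.full((4, abs(by)), 0.25)
    if by > 0:
        return np.hstack([pad, mat[:, :-by]])
    return np.hstack([mat[:, -by:], pad])


def simulate_footprints(config: SimulationConfig,
                        truth: GroundTruth | None = None,
                        ) -> tuple[pd.DataFrame, list[PWM], ArchetypeMap,
                                   pd.DataFrame]:
    """Footprint scores, motifs, archetype map and coupled RNA matrix.

    Archetype 1 is the planted pioneer: its score profile is high in the
    unique-regime cell type's conditions. Every archetype has one
    planted driver gene whose RNA correlates with the archetype score at
    expectation `driver_correlation`, plus independent decoy genes.
    Motifs within an archetype are offset / reverse-complement variants
    of one seed PWM.
    """
    conds = list(config.conditions)
    if len(conds) < 3:
        raise ParameterError(
            "need >= 3 conditions for footprint/RNA correlation")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    labels = [condition_label(c) for c in conds]
    n_cond = len(conds)
    uniq = config.unique_cell_type
    uniq_ind = np.array([1.0 if ct == uniq else 0.0 for ct, _, _ in conds])

    arch_ids = list(range(1, config.n_archetypes + 1))
    arch_scores = {}
    for a in arch_ids:
        if a == 1:
            arch_scores[a] = 2.0 * uniq_ind + rng.normal(0, 0.3, n_cond)
        else:
            arch_scores[a] = rng.normal(0, 1.0, n_cond)

    motif_to_arch: dict[str, int] = {}
    pwms: list[PWM] = []
    scores_rows, score_index = [], []
    per_arch = [config.n_motifs // config.n_archetypes
                + (1 if i < config.n_motifs % config.n_archetypes else 0)
                for i in range(config.n_archetypes)]
    for a, n_members in zip(arch_ids, per_arch):
        seed_mat = _seed_pwm(rng)
        variants = [seed_mat, seed_mat[np.array([3, 2, 1, 0])][:, ::-1],
                    _shift(seed_mat, 1), _shift(seed_mat, -1),
                    _shift(seed_mat, 1)[np.array([3, 2, 1, 0])][:, ::-1]]
        for k in range(n_members):
            name = f"M{a}.{k + 1}"
            pwms.append(PWM(name, variants[k % len(variants)],
                            source="synthetic"))
            motif_to_arch[name] = a
            scores_rows.append(arch_scores[a]
                               + rng.normal(0, config.motif_noise_sd, n_cond))
            score_index.append(name)
    table = pd.DataFrame(scores_rows, index=pd.Index(score_index,
                                                     name="motif"),
                         columns=labels)

    r = config.driver_correlation
    rna_rows, genes = [], []
    driver_tf: dict[int, str] = {}
    arch_genes: dict[int, list[str]] = {}
    for a in arch_ids:
        s = arch_scores[a]
        z_s = (s - s.mean()) / s.std()
        driver = f"Tf{a}drv"
        eps = rng.normal(0, 1.0, n_cond)
        z = r * z_s + math.sqrt(max(0.0, 1.0 - r * r)) * eps
        rna_rows.append(8.0 + 2.0 * z)
        genes.append(driver)
        driver_tf[a] = driver
        members = [driver]
        for k in range(config.n_decoys):
            decoy = f"Tf{a}dec{k + 1}"
            rna_rows.append(8.0 + 2.0 * rng.normal(0, 1.0, n_cond))
            genes.append(decoy)
            members.append(decoy)
        arch_genes[a] = members
    rna = pd.DataFrame(rna_rows, index=pd.Index(genes, name="gene"),
                       columns=labels)
    amap = ArchetypeMap(motif_to_arch, genes=arch_genes)
    if truth is None:
        truth = GroundTruth()
    truth.driver_tf = driver_tf
    return table, pwms, amap, rna


def simulate_chip(config: SimulationConfig, truth: GroundTruth,
                  target_pattern: int, enrichment: float,
                  background: float = 0.05, peaks: PeakSet | None = None,
                  ) -> PeakSet:
    """ChIP peaks overlapping ~`enrichment` of the target-pattern elements.

    Elements carrying `target_pattern` receive an overlapping peak with
    probability `enrichment`; all others with probability `background`.
    Pass the PeakSet from :func:`simulate_accessibility` to reuse its
    coordinates (regenerated deterministically otherwise).
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ParameterError("enrichment must be in [0, 1]")
    if not 0.0 <= background <= 1.0:
        raise ParameterError("background must be in [0, 1]")
    if truth.element_pattern is None:
        raise ParameterError("truth has no element_pattern; run "
                             "simulate_accessibility first")
    if target_pattern not in set(truth.pattern_profile.index):
        raise ParameterError(f"unknown pattern_id {target_pattern}")
    if peaks is None:
        peaks, _, _, _ = simulate_accessibility(config)
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 2, int(target_pattern)]))
    is_target = (truth.element_pattern.reindex(peaks.ids) == target_pattern)
    prob = np.where(is_target.to_numpy(), enrichment, background)
    hit = rng.random(len(peaks)) < prob
    rows = []
    for i, (chrom, start, end, _eid) in enumerate(
            peaks.df.itertuples(index=False)):
        if not hit[i]:
            continue
        off = int(rng.integers(-100, 201))
        rows.append((chrom, start + off, start + off + 300,
                     f"chip_{len(rows) + 1}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    return PeakSet(df, sort=True)


def _place_nuclei(rng: np.random.Generator, img: ImageSimConfig,
                  classes: list[str], far_flags: list[bool]):
    h, w = img.shape
    r = img.radius_px
    margin = r + 2
    min_dist = 2 * r + 3  # 2r contact + guard so smoothed disks never merge
    center = (h / 2.0, w / 2.0)
    domain_r = 0.30 * min(h, w)
    far_r = 0.45 * min(h, w)
    placed: list[tuple[float, float]] = []
    attempts = 0
    for cls, far in zip(classes, far_flags):
        while True:
            attempts += 1
            if attempts > img.max_attempts:
                raise ParameterError(
                    "could not place nuclei without overlap; reduce "
                    "image.n_nuclei or radius_px")
            row = rng.uniform(margin, h - margin)
            col = rng.uniform(margin, w - margin)
            d_center = math.hypot(row - center[0], col - center[1])
            if far:
                if d_center <= far_r:
                    continue
            elif cls in ("p3", "V3") and d_center > domain_r:
                continue
            if all(math.hypot(row - pr, col - pc) >= min_dist
                   for pr, pc in placed):
                placed.append((row, col))
                break
    return placed


def simulate_sections(config: SimulationConfig,
                      ) -> tuple[list[ImageStack], GroundTruth]:
    """Render synthetic sections with planted nucleus classes.

    Nuclei are disks on a flat background; p3 (SOX2+NKX2.2+) and V3
    (NKX2.2-only) nuclei sit inside a central domain, `other`
    (SOX2-only) nuclei anywhere, and optional far NKX2.2+
    background-binding cells outside the positional-QC radius.
    Gaussian noise of sd `noise_sd` is added to every channel.
    """
    img = config.image
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    class_names = list(img.class_probs)
    probs = np.array([img.class_probs[c] for c in class_names], dtype=float)
    probs = probs / probs.sum()
    stacks: list[ImageStack] = []
    truth_tables: list[pd.DataFrame] = []
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    for si in range(img.n_sections):
        classes = [class_names[i] for i in
                   rng.choice(len(class_names), size=img.n_nuclei, p=probs)]
        far = [False] * img.n_nuclei
        for _ in range(img.n_far_nkx):
            classes.append("other")
            far.append(True)
        centers = _place_nuclei(rng, img, classes, far)
        tdtom = [bool(rng.random() < img.tdtomato_prob[c]) and not f
                 for c, f in zip(classes, far)]
        channels = {ch: np.full(img.shape, img.background)
                    for ch in ("DAPI", "SOX2", "NKX2.2", "tdTomato")}
        rows = []
        for (row, col), cls, td, f in zip(centers, classes, tdtom, far):
            disk = (rr - row) ** 2 + (cc - col) ** 2 <= img.radius_px ** 2
            means = dict(img.channel_means[cls])
            if f:  # far background-binding cell: NKX2.2 signal, no SOX2
                means["SOX2"] = img.background
                means["NKX2.2"] = img.channel_means["V3"]["NKX2.2"]
            for ch in ("DAPI", "SOX2", "NKX2.2"):
                channels[ch][disk] = means.get(ch, img.background)
            channels["tdTomato"][disk] = (img.tdtomato_on if td
                                          else img.tdtomato_off)
            rows.append((row, col, cls, td, f))
        if img.noise_sd > 0:
            for ch in channels:
                channels[ch] = np.clip(
                    channels[ch] + rng.normal(0, img.noise_sd, img.shape),
                    0, None)
        stacks.append(ImageStack(channels=channels, section_id=f"sec_{si + 1}"))
        truth_tables.append(pd.DataFrame(
            rows, columns=["centroid_row", "centroid_col", "cell_class",
                           "tdtomato", "far_background"]))
    truth = GroundTruth(nucleus_truth=truth_tables)
    return stacks, truth
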