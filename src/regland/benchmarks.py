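"""Validation studies run on the synthetic generator.

Each function performs one self-contained study — calibration, planted
recovery, or oracle equivalence — from scratch, and returns plain
numbers. They back both the acceptance test suite and the
`scripts/acceptance.py` report. Problem sizes are chosen so the whole
set completes in a few minutes on one CPU; docs/methods.md lists them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.metrics import adjusted_rand_score

from regland import cluster as cl
from regland import da
from regland import enrich as en
from regland import footprint as fp
from regland import imaging as im
from regland.counts import size_factors, vst
from regland.peaks import PeakSet
from regland.simulate import (
    GroundTruth,
    ImageSimConfig,
    SimulationConfig,
    simulate_accessibility,
    simulate_footprints,
    simulate_sections,
    simulate_two_group,
)


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0]
               % (2 ** 31))


def null_type_i_error(seed: int, n_repetitions: int = 20,
                      n_elements: int = 1000, nb_dispersion: float = 0.2,
                      alpha_nominal: float = 0.05) -> tuple[float, int]:
    """Empirical type-I error of the NB Wald test on null simulations."""
    rejected = total = 0
    for rep in range(n_repetitions):
        counts, ga, gb, _ = simulate_two_group(
            seed=_subseed(seed, 100 + rep), n_elements=n_elements,
            frac_differential=0.0, nb_dispersion=nb_dispersion)
        f = size_factors(counts)
        alpha = da.pooled_dispersion(counts, f, [ga, gb])
        res = da.wald_test(counts, f, ga, gb, alpha)
        rejected += int((res["pvalue"] < alpha_nominal).sum())
        total += len(res)
    return rejected / total, total


def da_recovery(seed: int, n_repetitions: int = 3, n_elements: int = 2000,
                frac_differential: float = 0.1) -> tuple[float, float, int]:
    """Sensitivity and empirical FDR of the full selection rule."""
    tp = fn = fp_ = 0
    for rep in range(n_repetitions):
        counts, ga, gb, lfc = simulate_two_group(
            seed=_subseed(seed, 200 + rep), n_elements=n_elements,
            frac_differential=frac_differential)
        f = size_factors(counts)
        alpha = da.pooled_dispersion(counts, f, [ga, gb])
        res = da.wald_test(counts, f, ga, gb, alpha)
        selected = set(da.select_differential(res))
        truth = set(lfc.index[lfc != 0])
        tp += len(selected & truth)
        fn += len(truth - selected)
        fp_ += len(selected - truth)
    sensitivity = tp / (tp + fn)
    fdr = fp_ / max(tp + fp_, 1)
    return sensitivity, fdr, n_repetitions * n_elements


def _planted_profiles(config: SimulationConfig):
    _peaks, counts, samples, truth = simulate_accessibility(config)
    f = size_factors(counts)
    norm = vst(counts, f)
    dynamic = truth.element_pattern.index[truth.element_pattern > 0]
    profiles = cl.build_profiles(norm, samples, dynamic)
    return profiles, samples, truth


def clustering_recovery(seed: int, k1: int = 30, k_final: int = 9,
                        stability_seeds: int = 5) -> tuple[float, float, int]:
    """ARI vs planted patterns and mean pairwise ARI across seeds."""
    config = SimulationConfig(seed=_subseed(seed, 300))
    profiles, _samples, truth = _planted_profiles(config)
    model = cl.two_stage_cluster(profiles, k1=k1, k_final=k_final,
                                 seed=_subseed(seed, 301))
    planted = truth.element_pattern.loc[profiles.values.index]
    ari = float(adjusted_rand_score(planted, model.merged))
    stability = cl.cluster_stability(
        profiles, k1=k1, k_final=k_final,
        seeds=[_subseed(seed, 310 + i) for i in range(stability_seeds)])
    return ari, stability, len(profiles.values)


def regime_accuracy(seed: int, n_simulations: int = 20) -> tuple[float, int]:
    """Fraction of end-to-end simulations with every regime call correct.

    Each simulation runs the full pipeline: counts -> size factors ->
    VST -> all pairwise Wald tests -> selection rule -> two-stage
    clustering -> labels -> regime classification.
    """
    correct = 0
    for rep in range(n_simulations):
        config = SimulationConfig(seed=_subseed(seed, 400 + rep))
        _peaks, counts, samples, truth = simulate_accessibility(config)
        f = size_factors(counts)
        norm = vst(counts, f)
        selected: set = set()
        for res in da.run_pairwise(counts, f, samples).values():
            selected |= set(da.select_differential(res))
        profiles = cl.build_profiles(norm, samples, sorted(selected))
        model = cl.two_stage_cluster(profiles, seed=_subseed(seed, 450 + rep))
        cl.label_clusters(model, profiles, samples)
        report = cl.classify_regime(model, profiles, samples)
        expected = {ct: ("differential_accessibility" if regime == "unique"
                         else "differential_binding")
                    for ct, regime in config.cell_types}
        got = report.table["regime"].to_dict()
        correct += int(all(got[ct] == exp for ct, exp in expected.items()))
    return correct / n_simulations, n_simulations


def driver_recovery(seed: int, n_simulations: int = 200,
                    n_decoys: int = 5) -> tuple[float, int]:
    """Fraction of (simulation, archetype) pairs ranking the planted
    driver TF first, at 12 conditions and driver correlation 0.9."""
    conditions = [(ct, day, sag)
                  for ct, sag in (("p0-1", 0), ("p2", 10), ("pMN", 100),
                                  ("p3", 500))
                  for day in (4, 5, 6)]
    hits = total = 0
    for rep in range(n_simulations):
        config = SimulationConfig(seed=_subseed(seed, 500 + rep),
                                  conditions=conditions, n_archetypes=8,
                                  n_motifs=48, n_decoys=n_decoys,
                                  driver_correlation=0.9)
        truth = GroundTruth()
        table, _pwms, amap, rna = simulate_footprints(config, truth)
        scores, _var = fp.archetype_scores(table, amap)
        ranked = fp.rank_candidate_tfs(scores, rna, amap.genes)
        top = ranked[ranked["rank"] == 1].set_index("archetype")["gene"]
        for arch, driver in truth.driver_tf.items():
            total += 1
            hits += int(top.loc[arch] == driver)
    return hits / total, total


def _random_peaks(rng, n, prefix):
    chroms = np.array(["chr1", "chr2", "chr3"])[rng.integers(0, 3, n)]
    starts = rng.integers(0, 200_000, n)
    lengths = rng.integers(1, 800, n)
    df = pd.DataFrame({"chrom": chroms, "start": starts,
                       "end": starts + lengths,
                       "id": [f"{prefix}{i}" for i in range(n)]})
    return PeakSet(df, sort=True)


def overlap_oracle_mismatches(seed: int, n: int = 1000) -> tuple[int, int]:
    """Sweep-line overlap flags vs the all-pairs brute-force oracle."""
    rng = np.random.default_rng(_subseed(seed, 600))
    query = _random_peaks(rng, n, "q")
    ref = _random_peaks(rng, n, "r")
    flags = en.overlaps(query, ref).flags
    mism = 0
    q = query.df
    r = ref.df
    for chrom in q["chrom"].unique():
        qs = q[q["chrom"] == chrom]
        rs = r[r["chrom"] == chrom]
        hit = ((qs["start"].to_numpy()[:, None] < rs["end"].to_numpy())
               & (rs["start"].to_numpy() < qs["end"].to_numpy()[:, None])
               ).any(axis=1)
        mism += int((flags.loc[qs["id"]].to_numpy() != hit).sum())
    return mism, n


def hypergeom_enumeration_error(n_universe: int = 10) -> tuple[float, int]:
    """Max |closed-form - exhaustive| upper-tail p over toy configurations."""
    max_err = 0.0
    cases = 0
    for k_universe in (2, 4, 6):
        for n_draw in (3, 5, 7):
            for k in range(0, min(k_universe, n_draw) + 1):
                total = hits = 0
                for subset in combinations(range(n_universe), n_draw):
                    total += 1
                    hits += sum(1 for s in subset if s < k_universe) >= k
                exact = hits / total
                closed = float(stats.hypergeom.sf(k - 1, n_universe,
                                                  k_universe, n_draw))
                max_err = max(max_err, abs(exact - closed))
                cases += 1
    return max_err, cases


def imaging_recovery(seed: int, n_noisefree: int = 6,
                     n_noisy: int = 50) -> tuple[float, float, int]:
    """Exact recovery at zero noise; total-count error at 10% noise.

    Noise sd 16 is 10% of the 160-unit separation between marker-on and
    marker-off class means. Returns (fraction of noise-free sections
    with exact tdTomato+ p3/V3 counts, max relative error of the summed
    counts over the noisy sections, n sections).
    """
    cfg0 = SimulationConfig(seed=_subseed(seed, 700), image=ImageSimConfig(
        n_sections=n_noisefree, noise_sd=0.0))
    stacks, truth = simulate_sections(cfg0)
    summaries, _cells = im.quantify_sections(stacks)
    exact = 0
    for s, tt in zip(summaries, truth.nucleus_truth):
        t_p3 = int(((tt.cell_class == "p3") & tt.tdtomato).sum())
        t_v3 = int(((tt.cell_class == "V3") & tt.tdtomato).sum())
        exact += int((s.n_p3_tdtom, s.n_v3_tdtom) == (t_p3, t_v3))
    exact_fraction = exact / n_noisefree

    cfg1 = SimulationConfig(seed=_subseed(seed, 701), image=ImageSimConfig(
        n_sections=n_noisy, noise_sd=16.0))
    stacks, truth = simulate_sections(cfg1)
    summaries, _cells = im.quantify_sections(stacks)
    pred = np.array([[s.n_p3_tdtom, s.n_v3_tdtom] for s in summaries])
    true = np.array([
        [int(((tt.cell_class == "p3") & tt.tdtomato).sum()),
         int(((tt.cell_class == "V3") & tt.tdtomato).sum())]
        for tt in truth.nucleus_truth])
    totals_pred = pred.sum(axis=0)
    totals_true = true.sum(axis=0)
    rel_err = float(np.max(np.abs(totals_pred - totals_true)
                           / totals_true))
    return exact_fraction, rel_err, n_noisefree + n_noisy


def pca_oracle_deviation(seed: int, n_elements: int = 50,
                         n_samples: int = 6) -> tuple[float, int]:
    """Max |coordinate| deviation from an eigendecomposition oracle."""
    rng = np.random.default_rng(_subseed(seed, 800))
    from regland.counts import NormalizedMatrix

    x = rng.normal(size=(n_elements, n_samples))
    norm = NormalizedMatrix(
        pd.DataFrame(x, index=[f"e{i}" for i in range(n_elements)],
                     columns=[f"s{j}" for j in range(n_samples)]),
        pd.Series(1.0, index=[f"s{j}" for j in range(n_samples)]))
    coords, _ve = cl.pca(norm, top_n=n_elements)
    xc = (x - x.mean(axis=1, keepdims=True)).T
    w, v = linalg.eigh(xc @ xc.T)
    w, v = w[::-1], v[:, ::-1]
    oracle = v * np.sqrt(np.clip(w, 0.0, None))
    dev = 0.0
    for k in range(n_samples - 1):  # last PC is the centering null space
        c = coords.iloc[:, k].to_numpy()
        o = oracle[:, k]
        dev = max(dev, min(np.max(np.abs(c - o)), np.max(np.abs(c + o))))
    return float(dev), n_elements


def size_factor_recovery_error(seed: int) -> tuple[float, int]:
    """Max relative error vs planted library factors (null accessibility)."""
    config = SimulationConfig(seed=_subseed(seed, 810), n_elements=1000,
                              effect_log2fc=0.0)
    _peaks, counts, _samples, truth = simulate_accessibility(config)
    est = size_factors(counts)
    planted = truth.library_factors / np.exp(
        np.mean(np.log(truth.library_factors)))
    return float(np.max(np.abs(est / planted - 1.0))), len(est)


def bh_oracle_error(seed: int, n_p: int = 5000) -> tuple[float, int]:
    """Max |BH padj - independent step-up oracle| on random p-values."""
    rng = np.random.default_rng(_subseed(seed, 820))
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=n_p)
    order = np.argsort(p)
    adj = np.empty(n_p)
    running = 1.0
    for rank in range(n_p, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n_p / rank)
        adj[i] = running
    got = multipletests(p, method="fdr_bh")[1]
    return float(np.max(np.abs(got - adj))), n_p
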