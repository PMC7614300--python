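"""TF footprint scores, motif archetypes and candidate-driver ranking.

A footprint is a local depletion of transposase insertions at a bound
motif inside open chromatin. The score here is a simple flank-vs-center
log ratio; imported footprint score tables (e.g. from bias-corrected
footprinting tools) flow into the same downstream operations.
Position-weight matrices with near-identical specificity are grouped
into archetypes (published mapping when available, PWM-similarity
clustering otherwise); archetype scores per condition are correlated
with member-TF RNA expression to rank candidate driver factors.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from regland.errors import ParameterError, ValidationError

BASES = "ACGT"
_RC = np.array([3, 2, 1, 0])  # A<->T, C<->G row permutation


@dataclass
class PWM:
    """Position probability matrix, rows A/C/G/T."""

    name: str
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValidationError(f"PWM {self.name!r}: need 4 rows (A,C,G,T)")
        if self.matrix.shape[1] < 4:
            raise ValidationError(f"PWM {self.name!r}: length < 4")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError(f"PWM {self.name!r}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[_RC][:, ::-1], self.source)


@dataclass
class ArchetypeMap:
    """Partition of motifs into archetypes, with optional TF gene lists."""

    motif_to_archetype: dict[str, int]
    genes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.motif_to_archetype:
            raise ValidationError("archetype map is empty")

    @property
    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for motif, arch in self.motif_to_archetype.items():
            out.setdefault(arch, []).append(motif)
        return out


def read_pfm(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PFM text (counts or probabilities).

    Blocks are ``>name`` followed by four rows ``A [ 1 2 3 ]`` (or bare
    numbers); counts are normalized per column.
    """
    path = Path(path)
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValidationError(f"motif {name!r}: expected 4 rows, got {len(rows)}")
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise ValidationError(f"motif {name!r}: ragged rows")
        mat = np.asarray(rows, dtype=float)
        colsum = mat.sum(axis=0)
        if (colsum <= 0).any():
            raise ValidationError(f"motif {name!r}: zero column sum")
        pwms.append(PWM(name, mat / colsum, source=path.name))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = []
            else:
                nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", line)
                rows.append([float(v) for v in nums])
    flush()
    return pwms


def write_pfm(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for base, row in zip(BASES, p.matrix):
                fh.write(f"{base} [ " + " ".join(f"{v:.6f}" for v in row) + " ]\n")


def footprint_score(insertion_profile, center_width: int,
                    flank_width: int, pseudocount: float = 1.0) -> float:
    """Flank-vs-center insertion depletion: log2((flank+c)/(center+c)).

    The center window of `center_width` positions sits in the middle of
    the profile with `flank_width` positions on each side immediately
    adjacent. Positive scores mean protection (a footprint).
    """
    prof = np.asarray(insertion_profile, dtype=float)
    if (prof < 0).any():
        raise ParameterError("insertion counts must be >= 0")
    need = center_width + 2 * flank_width
    if len(prof) < need:
        raise ParameterError(
            f"profile length {len(prof)} < center_width + 2*flank_width = {need}"
        )
    mid = len(prof) // 2
    c0 = mid - center_width // 2
    c1 = c0 + center_width
    left = prof[c0 - flank_width:c0]
    right = prof[c1:c1 + flank_width]
    center_mean = prof[c0:c1].mean()
    flank_mean = np.concatenate([left, right]).mean()
    return float(np.log2((flank_mean + pseudocount) / (center_mean + pseudocount)))


def differential_footprints(table: pd.DataFrame,
                            pair: tuple[str, str]) -> pd.DataFrame:
    """Per-motif footprint change between two conditions, z-scored against
    the all-motif background.

    delta = score_B - score_A; z = (delta - median(delta)) /
    (1.4826 * MAD); p = two-sided normal tail. Needs >= 10 motifs for
    the background to be meaningful.
    """
    cond_a, cond_b = pair
    for c in pair:
        if c not in table.columns:
            raise ValidationError(f"condition {c!r} not in footprint table")
    if len(table) < 10:
        raise ValidationError("need >= 10 motifs to define a background")
    delta = table[cond_b] - table[cond_a]
    med = delta.median()
    mad = float(np.median(np.abs(delta - med)))
    scale = 1.4826 * mad
    if scale == 0:
        z = pd.Series(0.0, index=delta.index)
    else:
        z = (delta - med) / scale
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"delta": delta, "z": z, "pvalue": p},
                        index=table.index)


def select_variable_motifs(diff_results: dict[str, pd.DataFrame],
                           top_pct: float = 5.0) -> set[str]:
    """Union over comparisons of the top |delta| and smallest-p motifs.

    Per comparison, ceil(top_pct/100 * n) motifs are taken by descending
    |delta| and, separately, by ascending p; ties broken by motif name
    so the selection is deterministic.
    """
    if not diff_results:
        raise ValidationError("no differential-footprint results supplied")
    selected: set[str] = set()
    for res in diff_results.values():
        n_take = math.ceil(top_pct / 100.0 * len(res))
        by_delta = res.assign(absd=res["delta"].abs()) \
                      .sort_index().sort_values("absd", ascending=False,
                                                kind="mergesort")
        by_p = res.sort_index().sort_values("pvalue", kind="mergesort")
        selected |= set(by_delta.index[:n_take])
        selected |= set(by_p.index[:n_take])
    return selected


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 4) -> float:
    """Max over ungapped offsets and reverse complement of the mean
    column-wise Pearson correlation over the aligned region."""

    def best_offset(m1: np.ndarray, m2: np.ndarray) -> float:
        l1, l2 = m1.shape[1], m2.shape[1]
        best = -1.0
        for off in range(-(l2 - min_overlap), l1 - min_overlap + 1):
            s1 = max(0, off)
            e1 = min(l1, off + l2)
            if e1 - s1 < min_overlap:
                continue
            c1 = m1[:, s1:e1]
            c2 = m2[:, s1 - off:e1 - off]
            cors = []
            for j in range(c1.shape[1]):
                x, y = c1[:, j], c2[:, j]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    cors.append(0.0)
                else:
                    cors.append(float(np.corrcoef(x, y)[0, 1]))
            best = max(best, float(np.mean(cors)))
        return best

    fwd = best_offset(a.matrix, b.matrix)
    rev = best_offset(a.matrix, b.reverse_complement().matrix)
    return max(fwd, rev)


def cluster_archetypes(motifs: list[PWM], similarity_min: float = 0.8,
                       min_overlap: int = 4) -> ArchetypeMap:
    """Group motifs into archetypes by PWM-similarity clustering.

    Average-linkage hierarchical clustering of 1 - similarity, cut at
    1 - similarity_min. Used when no published motif -> archetype mapping
    file is supplied (a supplied mapping always wins).
    """
    if not motifs:
        raise ValidationError("no motifs supplied")
    names = [m.name for m in motifs]
    if len(motifs) == 1:
        return ArchetypeMap({names[0]: 1})
    n = len(motifs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = pwm_similarity(motifs[i], motifs[j],
                                                   min_overlap=min_overlap)
    dist = squareform(np.clip(1.0 - sim, 0.0, None), checks=False)
    tree = hierarchy.linkage(dist, method="average")
    assign = hierarchy.fcluster(tree, t=1.0 - similarity_min,
                                criterion="distance")
    return ArchetypeMap({name: int(a) for name, a in zip(names, assign)})


def read_archetype_map(path: str | Path) -> ArchetypeMap:
    """Two-column TSV motif<TAB>archetype_id (published mapping mode)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["motif", "archetype"])
    return ArchetypeMap({str(m): int(a) for m, a in
                         zip(df["motif"], df["archetype"])})


def archetype_scores(table: pd.DataFrame, amap: ArchetypeMap,
                     condition_subset: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Mean member-motif score per archetype and condition.

    Returns (archetype x condition matrix, archetype variability ranked
    descending). Variability is the variance across `condition_subset`
    (all conditions by default).
    """
    unmapped = [m for m in table.index if m not in amap.motif_to_archetype]
    if unmapped:
        raise ValidationError(f"unmapped motif(s): {unmapped[:10]}")
    arch = pd.Series({m: amap.motif_to_archetype[m] for m in table.index})
    scores = table.groupby(arch).mean()
    scores.index.name = "archetype"
    sub = scores[condition_subset] if condition_subset else scores
    variability = sub.var(axis=1, ddof=1).sort_values(ascending=False)
    variability.name = "variability"
    return scores, variability


def rank_candidate_tfs(arch_scores: pd.DataFrame, rna: pd.DataFrame,
                       membership: dict[int, list[str]]) -> pd.DataFrame:
    """Pearson correlation of member-TF RNA with archetype scores.

    Correlations are computed across the conditions shared by both
    matrices (>= 3 required); within each archetype genes are ranked by
    descending r, ties broken by gene name; zero-variance genes get
    undefined r (NaN) and rank last with ``r_defined = False``. Member
    genes absent from the RNA matrix are reported and skipped.
    """
    shared = [c for c in arch_scores.columns if c in rna.columns]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared conditions for correlation")
    rows = []
    for arch, genes in membership.items():
        if arch not in arch_scores.index:
            raise ValidationError(f"archetype {arch} missing from scores")
        s = arch_scores.loc[arch, shared].to_numpy(dtype=float)
        missing = [g for g in genes if g not in rna.index]
        if missing:
            warnings.warn(f"archetype {arch}: RNA missing for {missing}",
                          stacklevel=2)
        for gene in genes:
            if gene not in rna.index:
                continue
            e = rna.loc[gene, shared].to_numpy(dtype=float)
            if e.std() == 0 or s.std() == 0:
                rows.append((arch, gene, np.nan, False))
            else:
                r = float(np.corrcoef(s, e)[0, 1])
                rows.append((arch, gene, r, True))
    out = pd.DataFrame(rows, columns=["archetype", "gene", "pearson_r",
                                      "r_defined"])
    out = out.sort_values(["archetype", "r_defined", "pearson_r", "gene"],
                          ascending=[True, False, False, True],
                          kind="mergesort")
    out["rank"] = out.groupby("archetype").cumcount() + 1
    return out.reset_index(drop=True)
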