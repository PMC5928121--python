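"""In-vivo stage: contact-decay estimation, HOT-loop enrichment, and
synthetic generators that emulate the real inputs.

The contact-decay rate alpha is the local slope of log(contact signal)
against log(genomic separation): contact probability falls off as
``s^-alpha`` with linear separation ``s``, and more negative local
slopes indicate less compact chromatin.  For each 50 kb window the
slope is estimated by ordinary least squares over the nearest ``flank``
windows on each side (self-contacts excluded, zero-signal pairs
dropped).

HOT regions (highly occupied targets: sub-kilobase loci bound
promiscuously by most chromatin proteins) are tested for enrichment at
chromosomal loops with a binomial null: a HOT "overlaps" when its
midpoint falls inside the merged loop footprint, and the null overlap
probability is the merged footprint divided by the genome size covered
by the chromosome-sizes table.

The pipeline accepts an already-normalized binned matrix; upstream read
mapping and normalization are out of scope.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContactMatrixBinned",
    "GenomicIntervalSet",
    "DecayProfile",
    "EnrichmentResult",
    "DecayComparison",
    "read_intervals",
    "read_genome_sizes",
    "read_matrix",
    "contact_decay",
    "hot_loop_enrichment",
    "decay_at_intervals",
    "synth_hic",
    "synth_intervals",
]


@dataclass
class ContactMatrixBinned:
    """Square per-chromosome matrix of normalized contact signal."""

    matrix: np.ndarray
    bin_size: int = 50_000
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("binned contact matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("binned contact matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("binned contact matrix must be non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def to_dense_text(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t")

    def to_sparse_text(self, path: str | Path) -> None:
        ii, jj = np.nonzero(np.triu(self.matrix))
        with open(path, "w") as fh:
            fh.write("# i\tj\tsignal\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{self.matrix[i, j]:.10g}\n")


def read_matrix(path: str | Path, bin_size: int = 50_000, chrom: str = "chr1") -> ContactMatrixBinned:
    """Read a dense-text or sparse 3-column (i, j, signal) matrix."""
    path = Path(path)
    first_data = None
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first_data = line
                break
    if first_data is None:
        raise ValueError(f"{path}: empty matrix file")
    n_fields = len(first_data.split())
    if n_fields == 3:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["i", "j", "v"])
        n = int(max(df["i"].max(), df["j"].max())) + 1
        m = np.zeros((n, n))
        m[df["i"], df["j"]] = df["v"]
        m[df["j"], df["i"]] = df["v"]
    else:
        m = np.loadtxt(path)
    return ContactMatrixBinned(matrix=m, bin_size=bin_size, chrom=chrom)


@dataclass
class GenomicIntervalSet:
    """Strand-free intervals in 0-based half-open coordinates, sorted
    within each chromosome."""

    df: pd.DataFrame
    role: str = ""

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"interval table needs columns {sorted(required)}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval {bad}: start must be < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def midpoints(self) -> pd.DataFrame:
        out = self.df[["chrom"]].copy()
        out["mid"] = (self.df["start"] + self.df["end"]) // 2
        return out

    def merged(self) -> "GenomicIntervalSet":
        """Union of the intervals (per chromosome)."""
        rows = []
        for chrom, grp in self.df.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return GenomicIntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]), role=self.role
        )

    def footprint(self) -> int:
        merged = self.merged().df
        return int((merged["end"] - merged["start"]).sum())


_DIALECTS = ("bed", "arrowhead-domainlist", "hot-fasta-headers")
_LOCUS_RE = re.compile(r"([\w.]+):(\d+)-(\d+)")


def read_intervals(
    path: str | Path,
    dialect: str,
    role: str = "",
    interpretation: str = "domain",
    anchor_width: int = 50_000,
    chrom_prefix: str = "chr",
) -> GenomicIntervalSet:
    """Read genomic intervals from one of three dialects.

    ``bed``
        3+ column BED; already 0-based half-open.
    ``arrowhead-domainlist``
        tab-separated domain calls with columns chr1/x1/x2/chr2/y1/y2
        (header optional).  ``interpretation='domain'`` keeps the body
        [x1, x2); ``'anchors'`` emits the two boundary intervals of
        width ``anchor_width`` instead.  Chromosome names are normalized
        to carry ``chrom_prefix``.
    ``hot-fasta-headers``
        FASTA whose headers carry ``chrom:start-end`` locus strings in
        1-based inclusive coordinates (converted on read).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect '{dialect}'; choose from {_DIALECTS}")
    path = Path(path)
    if dialect == "bed":
        rows = _read_bed(path)
    elif dialect == "arrowhead-domainlist":
        rows = _read_arrowhead(path, interpretation, anchor_width, chrom_prefix)
    else:
        rows = _read_fasta_headers(path)
    if not rows:
        warnings.warn(f"{path}: no intervals parsed (empty set)", stacklevel=2)
        return GenomicIntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), role=role)
    return GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), role=role)


def _read_bed(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: BED record needs >= 3 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed coordinates") from exc
    return rows


def _read_arrowhead(path: Path, interpretation: str, anchor_width: int, chrom_prefix: str) -> list[tuple]:
    if interpretation not in ("domain", "anchors"):
        raise ValueError("interpretation must be 'domain' or 'anchors'")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("chr1", "chrom1") and not parts[1].isdigit():
                continue  # header row
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: domain record needs >= 6 fields")
            chrom = parts[0]
            if chrom_prefix and not chrom.startswith(chrom_prefix):
                chrom = chrom_prefix + chrom
            try:
                x1, x2 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed coordinates") from exc
            if interpretation == "domain":
                rows.append((chrom, x1, x2))
            else:
                rows.append((chrom, x1, min(x1 + anchor_width, x2)))
                rows.append((chrom, max(x2 - anchor_width, x1), x2))
    return rows


def _read_fasta_headers(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(">"):
                continue
            m = _LOCUS_RE.search(line)
            if m is None:
                raise ValueError(f"{path}: line {lineno}: header carries no chrom:start-end locus")
            start_1based = int(m.group(2))
            end_inclusive = int(m.group(3))
            rows.append((m.group(1), start_1based - 1, end_inclusive))
    return rows


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chromosome-sizes TSV -> {chrom: length}."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


@dataclass
class DecayProfile:
    """Per-window contact-decay slope estimates for one chromosome."""

    alphas: np.ndarray
    n_points: np.ndarray
    chrom: str
    bin_size: int
    flank: int

    @property
    def n_windows(self) -> int:
        return self.alphas.size

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# chrom\tstart\tend\talpha\n")
            for i, a in enumerate(self.alphas):
                if np.isfinite(a):
                    fh.write(f"{self.chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{a:.6g}\n")


def contact_decay(
    matrix: ContactMatrixBinned,
    flank: int = 20,
    min_points: int = 5,
    pseudocount: float | None = None,
) -> DecayProfile:
    """Windowed contact-decay slopes.

    For window ``i`` the slope of ``log(signal(i, i +/- d))`` against
    ``log(d * bin_size)`` is estimated over ``d = 1..flank`` on both
    sides pooled; self-contacts are never used.  Zero-signal pairs are
    dropped (or replaced by ``pseudocount`` when one is supplied);
    windows with fewer than ``min_points`` usable pairs -- including
    all-zero rows -- yield a missing (NaN) estimate.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    m = matrix.matrix
    n = matrix.n_bins
    alphas = np.full(n, np.nan)
    n_points = np.zeros(n, dtype=np.int64)
    log_bin = np.log(matrix.bin_size)
    log_d = np.log(np.arange(1, flank + 1))
    for i in range(n):
        lo = max(0, i - flank)
        hi = min(n, i + flank + 1)
        d_left = np.arange(1, i - lo + 1)
        d_right = np.arange(1, hi - i)
        xs = np.concatenate([log_d[d_left - 1], log_d[d_right - 1]]) + log_bin
        ys = np.concatenate([m[i, i - d_left], m[i, i + d_right]])
        if pseudocount is not None:
            ys = ys + pseudocount
        keep = ys > 0
        if keep.sum() < min_points:
            continue
        slope = np.polyfit(xs[keep], np.log(ys[keep]), 1)[0]
        alphas[i] = slope
        n_points[i] = int(keep.sum())
    return DecayProfile(alphas=alphas, n_points=n_points, chrom=matrix.chrom,
                        bin_size=matrix.bin_size, flank=flank)


@dataclass
class EnrichmentResult:
    """Binomial test of HOT midpoints against a loop footprint null."""

    n_hots: int
    n_overlapping: int
    n_expected: float
    p_null: float
    p_value: float
    rule: str = "midpoint"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_hots": self.n_hots,
                "n_overlapping": self.n_overlapping,
                "n_expected": self.n_expected,
                "p_null": self.p_null,
                "p_value": self.p_value,
                "rule": self.rule,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _midpoint_inside(mids: pd.DataFrame, merged: GenomicIntervalSet) -> np.ndarray:
    """Boolean mask: midpoint lies inside some merged interval."""
    inside = np.zeros(len(mids), dtype=bool)
    for chrom, grp in mids.groupby("chrom", sort=False):
        sub = merged.df[merged.df["chrom"] == chrom]
        if sub.empty:
            continue
        flat = np.empty(2 * len(sub), dtype=np.int64)
        flat[0::2] = sub["start"].to_numpy()
        flat[1::2] = sub["end"].to_numpy()
        pos = np.searchsorted(flat, grp["mid"].to_numpy(), side="right")
        inside[grp.index] = pos % 2 == 1
    return inside


def hot_loop_enrichment(
    hots: GenomicIntervalSet,
    loops: GenomicIntervalSet,
    genome_sizes: dict[str, int],
    rule: str = "midpoint",
) -> EnrichmentResult:
    """Enrichment of HOTs inside the merged loop footprint.

    Null model: each HOT lands inside the footprint independently with
    probability footprint / genome size; the p-value is the upper
    binomial tail at the observed overlap count.  ``rule='any-overlap'``
    counts a HOT when its interval intersects the footprint instead of
    the midpoint criterion (HOTs are sub-kilobase, so the two rules
    nearly coincide).
    """
    if rule not in ("midpoint", "any-overlap"):
        raise ValueError("rule must be 'midpoint' or 'any-overlap'")
    missing = set(hots.df["chrom"]) - set(genome_sizes)
    if missing:
        raise ValueError(f"chromosomes present in HOTs but absent from genome sizes: {sorted(missing)}")
    n_hots = len(hots)
    total_bp = sum(genome_sizes.values())
    if len(loops) == 0:
        return EnrichmentResult(n_hots=n_hots, n_overlapping=0, n_expected=0.0,
                                p_null=0.0, p_value=1.0, rule=rule)
    merged = loops.merged()
    footprint = merged.footprint()
    p_null = footprint / total_bp
    if rule == "midpoint":
        k = int(_midpoint_inside(hots.midpoints(), merged).sum())
    else:
        k = 0
        for chrom, grp in hots.df.groupby("chrom", sort=False):
            sub = merged.df[merged.df["chrom"] == chrom]
            if sub.empty:
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            for _, row in grp.iterrows():
                if np.any((row["start"] < e) & (row["end"] > s)):
                    k += 1
    p_value = float(stats.binom.sf(k - 1, n_hots, p_null)) if n_hots else 1.0
    return EnrichmentResult(
        n_hots=n_hots, n_overlapping=k, n_expected=float(n_hots * p_null),
        p_null=float(p_null), p_value=p_value, rule=rule,
    )


@dataclass
class DecayComparison:
    """Welch two-sample comparison of decay slopes, genome vs HOTs."""

    mean_all: float
    mean_at: float
    delta: float
    statistic: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    n_all: int
    n_at: int
    degenerate: bool = False


def decay_at_intervals(
    profiles: DecayProfile | list[DecayProfile],
    hots: GenomicIntervalSet,
) -> DecayComparison:
    """Compare decay slopes genome-wide against windows containing a HOT.

    Sample A pools every finite window estimate; sample B takes, for
    each HOT, the estimate of the window containing its midpoint (one
    value per HOT, so windows hosting several HOTs contribute several
    times).  Welch's unequal-variance t test with Welch-Satterthwaite
    degrees of freedom; the confidence interval is for mean(A) - mean(B).
    """
    if isinstance(profiles, DecayProfile):
        profiles = [profiles]
    by_chrom = {p.chrom: p for p in profiles}
    sample_a = np.concatenate([p.alphas[np.isfinite(p.alphas)] for p in profiles])
    vals_b = []
    for chrom, grp in hots.midpoints().groupby("chrom", sort=False):
        prof = by_chrom.get(chrom)
        if prof is None:
            continue
        w = (grp["mid"].to_numpy() // prof.bin_size).astype(int)
        w = w[(w >= 0) & (w < prof.n_windows)]
        a = prof.alphas[w]
        vals_b.extend(a[np.isfinite(a)])
    sample_b = np.asarray(vals_b)
    if sample_b.size == 0:
        raise ValueError("no HOT falls in a window with a decay estimate")
    mean_a = float(sample_a.mean())
    mean_b = float(sample_b.mean())
    delta = mean_a - mean_b
    # a few ulps of spread from summation rounding still counts as constant
    tol_a = 1e-12 * max(1.0, abs(mean_a))
    tol_b = 1e-12 * max(1.0, abs(mean_b))
    if sample_a.std(ddof=1) <= tol_a and sample_b.std(ddof=1) <= tol_b:
        return DecayComparison(
            mean_all=mean_a, mean_at=mean_b, delta=delta, statistic=np.nan,
            df=np.nan, p_value=np.nan, ci_low=np.nan, ci_high=np.nan,
            n_all=sample_a.size, n_at=sample_b.size, degenerate=True,
        )
    res = stats.ttest_ind(sample_a, sample_b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return DecayComparison(
        mean_all=mean_a, mean_at=mean_b, delta=delta,
        statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        ci_low=float(ci.low), ci_high=float(ci.high),
        n_all=sample_a.size, n_at=sample_b.size,
    )


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------


def synth_hic(
    n_bins: int = 400,
    bin_size: int = 50_000,
    alpha_background: float = -1.22,
    alpha_patches: tuple = (),
    loop_peaks: tuple = (),
    noise_dispersion: float = 0.0,
    base_signal: float = 1000.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[ContactMatrixBinned, dict]:
    """Synthetic binned contact matrix with locally varying decay.

    ``signal(i, j) = base * |i-j| ** ((alpha_i + alpha_j) / 2)`` with a
    per-window exponent field (background plus patches), multiplied by
    symmetric log-normal noise of the given dispersion, plus Gaussian
    loop peaks ``(i, j, strength)`` of width 2 bins.  The default
    background slope matches typical mammalian Hi-C decay.  Returns the
    matrix together with a truth record of every generating parameter.
    """
    if alpha_background >= 0:
        raise ValueError("decay exponents must be negative")
    alpha = np.full(n_bins, float(alpha_background))
    for (lo, hi), a in alpha_patches:
        if a >= 0:
            raise ValueError("decay exponents must be negative")
        if not (0 <= lo < hi <= n_bins):
            raise ValueError(f"patch range ({lo}, {hi}) outside the matrix")
        alpha[lo:hi] = a
    idx = np.arange(n_bins)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        exponent = (alpha[:, None] + alpha[None, :]) / 2.0
        m = base_signal * np.where(sep > 0, sep, 1.0) ** exponent
    np.fill_diagonal(m, base_signal)
    rng = np.random.default_rng(seed)
    if noise_dispersion > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_dispersion, size=(n_bins, n_bins))
        noise = np.triu(noise) + np.triu(noise, 1).T
        m = m * noise
    for i, j, strength in loop_peaks:
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"loop peak ({i}, {j}) outside the matrix")
        bump = strength * base_signal * np.exp(
            -((idx[:, None] - i) ** 2 + (idx[None, :] - j) ** 2) / (2.0 * 2.0**2)
        )
        m = m + bump + bump.T
    truth = {
        "n_bins": n_bins,
        "bin_size": bin_size,
        "alpha_background": alpha_background,
        "alpha_patches": list(alpha_patches),
        "alpha_per_window": alpha.tolist(),
        "loop_peaks": list(loop_peaks),
        "noise_dispersion": noise_dispersion,
        "base_signal": base_signal,
        "seed": seed,
    }
    return ContactMatrixBinned(matrix=m, bin_size=bin_size, chrom=chrom), truth


def synth_intervals(
    n_hots: int = 1000,
    n_loops: int = 200,
    loop_length: int = 200_000,
    hot_length: int = 600,
    genome_sizes: dict[str, int] | None = None,
    enrichment_rho: float = 1.0,
    seed: int = 0,
) -> tuple[GenomicIntervalSet, GenomicIntervalSet, dict]:
    """Synthetic HOT and loop interval sets with controlled enrichment.

    Loops are placed uniformly; each HOT midpoint falls inside the
    merged loop footprint with probability ``rho * p_null`` (capped at
    1), else uniformly outside, so ``rho = 1`` reproduces the null and
    larger ``rho`` gives a ``rho``-fold enrichment in expectation.
    Returns (hots, loops, truth record).
    """
    if genome_sizes is None:
        genome_sizes = {"chr1": 50_000_000, "chr2": 50_000_000}
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()

    loop_rows = []
    for _ in range(n_loops):
        ci = rng.choice(len(chroms), p=weights)
        start = int(rng.integers(0, genome_sizes[chroms[ci]] - loop_length))
        loop_rows.append((chroms[ci], start, start + loop_length))
    loops = GenomicIntervalSet(
        pd.DataFrame(loop_rows, columns=["chrom", "start", "end"]) if loop_rows
        else pd.DataFrame(columns=["chrom", "start", "end"]),
        role="loop",
    )

    total_bp = int(sizes.sum())
    if n_loops:
        merged = loops.merged().df
        footprint = int((merged["end"] - merged["start"]).sum())
    else:
        merged = pd.DataFrame(columns=["chrom", "start", "end"])
        footprint = 0
    p_null = footprint / total_bp
    p_in = enrichment_rho * p_null
    if p_in > 1.0:
        raise ValueError(f"enrichment rho {enrichment_rho} infeasible: rho * p_null = {p_in:.3f} > 1")

    half = hot_length // 2
    if n_loops:
        seg_len = (merged["end"] - merged["start"]).to_numpy()
        seg_w = seg_len / seg_len.sum()
    hot_rows = []
    n_inside = 0
    for _ in range(n_hots):
        if n_loops and rng.random() < p_in:
            si = rng.choice(len(merged), p=seg_w)
            mid = int(rng.integers(merged["start"].iat[si], merged["end"].iat[si]))
            chrom = merged["chrom"].iat[si]
            n_inside += 1
        else:
            while True:
                ci = rng.choice(len(chroms), p=weights)
                chrom = chroms[ci]
                mid = int(rng.integers(half, genome_sizes[chrom] - half))
                sub = merged[merged["chrom"] == chrom]
                if sub.empty or not ((sub["start"] <= mid) & (mid < sub["end"])).any():
                    break
        hot_rows.append((chrom, max(0, mid - half), mid + half))
    hots = GenomicIntervalSet(
        pd.DataFrame(hot_rows, columns=["chrom", "start", "end"]), role="HOT"
    )
    truth = {
        "n_hots": n_hots,
        "n_loops": n_loops,
        "p_null": p_null,
        "enrichment_rho": enrichment_rho,
        "n_inside_realized": n_inside,
        "seed": seed,
    }
    return hots, loops, truth
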