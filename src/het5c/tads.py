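"""Directionality-Index computation, HMM segmentation into biased states,
TAD/border extraction per replicate, and cross-replicate consensus calls.

Per bin, A is the sum of interaction scores to bins up to ``window`` bp
upstream and B the corresponding downstream sum; with E = (A + B) / 2,

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

and DI = 0 when A = B. Positive DI marks downstream bias (domain starts),
negative DI upstream bias (domain ends). The DI track is discretized into
quantile levels and segmented with a 3-state discrete-emission HMM fitted by
EM from seeded initializations; state labels are assigned from each state's
mean decoded DI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import CategoricalHMM

from .quant import BinnedContactMatrix

logger = logging.getLogger(__name__)

DOWNSTREAM = "downstream_bias"
NO_BIAS = "no_bias"
UPSTREAM = "upstream_bias"

__all__ = [
    "DIProfile",
    "BiasHMM",
    "TAD",
    "TADSet",
    "compute_directionality_index",
    "fit_bias_hmm",
    "extract_tads",
    "consensus_boundaries",
    "boundary_match",
    "DOWNSTREAM",
    "NO_BIAS",
    "UPSTREAM",
]


@dataclass
class DIProfile:
    chrom: str
    bin_size: int
    window: int
    bin_starts: np.ndarray
    di: np.ndarray
    a: np.ndarray  # upstream sums
    b: np.ndarray  # downstream sums
    e: np.ndarray  # (a + b) / 2
    no_data: np.ndarray  # bins with A = B = 0

    def __len__(self) -> int:
        return len(self.bin_starts)


@dataclass
class BiasHMM:
    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray  # 3 x K
    discretization_edges: np.ndarray
    state_labels: dict[int, str]
    log_likelihood: float
    converged: bool


@dataclass(frozen=True)
class TAD:
    chrom: str
    start: int
    end: int
    replicate_id: str


@dataclass
class TADSet:
    tads: list[TAD] = field(default_factory=list)
    borders: list[tuple[str, int, int]] = field(default_factory=list)
    consensus: bool = False
    support_fraction: float | None = None

    def __post_init__(self) -> None:
        self.tads = sorted(self.tads, key=lambda t: (t.chrom, t.start))
        by_chrom: dict[str, list[TAD]] = {}
        for t in self.tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            reps: dict[str, list[TAD]] = {}
            for t in ts:
                reps.setdefault(t.replicate_id, []).append(t)
            for rep_ts in reps.values():
                for prev, cur in zip(rep_ts, rep_ts[1:]):
                    if cur.start < prev.end:
                        raise ValueError(
                            f"overlapping TADs on {chrom}: {prev} / {cur}"
                        )

    def boundaries(self) -> dict[str, list[int]]:
        """Per-chromosome sorted unique TAD edge positions."""
        out: dict[str, set[int]] = {}
        for t in self.tads:
            out.setdefault(t.chrom, set()).update((t.start, t.end))
        return {c: sorted(v) for c, v in out.items()}


def compute_directionality_index(
    matrix: BinnedContactMatrix, window: int = 100_000
) -> DIProfile:
    """Per-bin DI over a ``window`` x ``window`` square along the diagonal.

    Requires non-overlapping bins (bin_step == bin_size) and window a
    multiple of bin_size. Windows truncated at chromosome ends use the
    available span. Bins with A = B = 0 get DI = 0 and the no-data flag.
    """
    if matrix.bin_step != matrix.bin_size:
        raise ValueError("DI requires non-overlapping bins (bin_step == bin_size)")
    if window % matrix.bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    nb = window // matrix.bin_size
    n = matrix.n_bins
    a = np.zeros(n)
    b = np.zeros(n)
    for (i, j), v in matrix.items():
        if i == j:
            continue
        d = j - i  # j > i by canonical storage
        if d <= nb:
            b[i] += v  # j is downstream of i
            a[j] += v  # i is upstream of j
    e = (a + b) / 2.0
    di = np.zeros(n)
    for i in range(n):
        if a[i] == b[i]:
            continue
        sign = 1.0 if b[i] > a[i] else -1.0
        di[i] = sign * ((a[i] - e[i]) ** 2 / e[i] + (b[i] - e[i]) ** 2 / e[i])
    no_data = (a == 0) & (b == 0)
    return DIProfile(
        chrom=matrix.chrom,
        bin_size=matrix.bin_size,
        window=window,
        bin_starts=matrix.bin_starts.copy(),
        di=di,
        a=a,
        b=b,
        e=e,
        no_data=no_data,
    )


def _label_states(di: np.ndarray, path: np.ndarray) -> dict[int, str]:
    """Rank states by mean decoded DI; the top state is downstream_bias only
    if its mean is positive, the bottom upstream_bias only if negative."""
    means = np.zeros(3)
    for s in range(3):
        sel = path == s
        means[s] = float(di[sel].mean()) if sel.any() else 0.0
    order = np.argsort(means)
    labels = {int(s): NO_BIAS for s in range(3)}
    if means[order[0]] < 0:
        labels[int(order[0])] = UPSTREAM
    if means[order[2]] > 0:
        labels[int(order[2])] = DOWNSTREAM
    return labels


def fit_bias_hmm(
    profile: DIProfile,
    k_levels: int = 7,
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[BiasHMM, np.ndarray]:
    """Discretize DI into ``k_levels`` quantile levels, fit a 3-state
    discrete-emission HMM by EM (``n_restarts`` seeded initializations, best
    log-likelihood wins, ties to the lowest restart index), and return the
    model plus the most-likely state-label path.

    Precondition: at least 2 * window / bin_size bins. A constant DI track
    short-circuits to an all-``no_bias`` path.
    """
    min_bins = 2 * profile.window // profile.bin_size
    if len(profile) < min_bins:
        raise ValueError(
            f"need >= {min_bins} bins for HMM calling, got {len(profile)}"
        )
    di = profile.di
    if np.ptp(di) == 0:
        edges = np.array([])
        model = BiasHMM(
            startprob=np.full(3, 1 / 3),
            transmat=np.full((3, 3), 1 / 3),
            emissionprob=np.full((3, k_levels), 1 / k_levels),
            discretization_edges=edges,
            state_labels={0: NO_BIAS, 1: NO_BIAS, 2: NO_BIAS},
            log_likelihood=0.0,
            converged=True,
        )
        return model, np.array([NO_BIAS] * len(di))

    edges = np.quantile(di, np.linspace(0, 1, k_levels + 1)[1:-1])
    symbols = np.searchsorted(edges, di, side="right").astype(int)
    obs = symbols.reshape(-1, 1)

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        hmm = CategoricalHMM(
            n_components=3,
            n_features=k_levels,
            n_iter=n_iter,
            tol=tol,
            init_params="",
            params="ste",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        hmm.startprob_ = np.full(3, 1 / 3)
        trans = np.full((3, 3), 0.05)
        np.fill_diagonal(trans, 0.90)
        trans += rng.uniform(0, 0.02, size=(3, 3))
        hmm.transmat_ = trans / trans.sum(axis=1, keepdims=True)
        # informative init: state 0 low symbols (upstream), 1 middle, 2 high
        em = np.ones((3, k_levels))
        levels = np.arange(k_levels)
        em[0] += 3.0 * (k_levels - 1 - levels) / max(k_levels - 1, 1)
        em[1] += 3.0 * (1 - np.abs(levels - (k_levels - 1) / 2) / ((k_levels - 1) / 2))
        em[2] += 3.0 * levels / max(k_levels - 1, 1)
        em += rng.uniform(0, 0.2, size=em.shape)
        hmm.emissionprob_ = em / em.sum(axis=1, keepdims=True)
        try:
            hmm.fit(obs)
            ll = float(hmm.score(obs))
        except Exception:  # numerical failure in one restart is tolerable
            logger.warning("HMM restart %d failed; skipping", r)
            continue
        if best is None or ll > best[0] + 1e-9:
            best = (ll, hmm)
    if best is None:
        raise RuntimeError("all HMM restarts failed")
    ll, hmm = best
    converged = bool(hmm.monitor_.converged)
    if not converged:
        logger.warning("EM did not converge within %d iterations; using best-so-far", n_iter)
    path = hmm.predict(obs)
    labels = _label_states(di, path)
    model = BiasHMM(
        startprob=hmm.startprob_.copy(),
        transmat=hmm.transmat_.copy(),
        emissionprob=hmm.emissionprob_.copy(),
        discretization_edges=edges,
        state_labels=labels,
        log_likelihood=ll,
        converged=converged,
    )
    label_path = np.array([labels[int(s)] for s in path])
    return model, label_path


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode as (label, start_index, end_index_inclusive)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    return runs


def extract_tads(
    label_path: np.ndarray,
    bin_starts: np.ndarray,
    bin_size: int,
    chrom: str,
    replicate_id: str = "rep",
    min_run: int = 2,
) -> TADSet:
    """Extract TADs from a state path: a TAD starts at the first bin of a
    downstream-bias run and ends at the last bin of the next upstream-bias
    run; intervening no-bias bins are interior. Biased runs shorter than
    ``min_run`` are absorbed into no-bias first. A downstream run with no
    following upstream run before the chromosome end is dropped and logged.
    Gaps between consecutive TADs become border intervals.
    """
    labels = np.asarray(label_path, dtype=object).copy()
    for lab, s, e in _runs(labels):
        if lab in (DOWNSTREAM, UPSTREAM) and (e - s + 1) < min_run:
            labels[s : e + 1] = NO_BIAS

    runs = _runs(labels)
    tads: list[TAD] = []
    i = 0
    while i < len(runs):
        lab, s, _ = runs[i]
        if lab != DOWNSTREAM:
            i += 1
            continue
        # find the next upstream run; intervening D/N runs are interior
        j = i + 1
        while j < len(runs) and runs[j][0] != UPSTREAM:
            j += 1
        if j == len(runs):
            logger.info(
                "open domain on %s at bin %d dropped (no closing upstream run)", chrom, s
            )
            break
        _, _, u_end = runs[j]
        tads.append(
            TAD(chrom, int(bin_starts[s]), int(bin_starts[u_end]) + bin_size, replicate_id)
        )
        i = j + 1

    borders = []
    for prev, cur in zip(tads, tads[1:]):
        if cur.start > prev.end:
            borders.append((chrom, prev.end, cur.start))
    return TADSet(tads=tads, borders=borders, consensus=False)


def _cluster_positions(
    entries: list[tuple[int, str]], tolerance: int
) -> list[list[tuple[int, str]]]:
    """Single-linkage clustering of 1-D positions: sort and split where the
    gap between neighbours exceeds ``tolerance``."""
    entries = sorted(entries)
    clusters: list[list[tuple[int, str]]] = []
    for pos, rep in entries:
        if clusters and pos - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append((pos, rep))
        else:
            clusters.append([(pos, rep)])
    return clusters


def consensus_boundaries(
    replicate_sets: list[TADSet],
    tolerance: int = 50_000,
    min_support: int = 2,
    bin_size: int | None = None,
) -> tuple[TADSet, dict]:
    """Cluster replicate boundaries (single linkage, linkage distance <=
    ``tolerance``); clusters supported by >= ``min_support`` distinct
    replicates yield a consensus boundary at the cluster median. Consensus
    TADs are re-derived between consecutive consensus boundaries. The report
    includes the fraction of replicate boundaries falling in supported
    clusters.
    """
    if len(replicate_sets) < 2:
        raise ValueError("consensus requires >= 2 replicate TAD sets")
    if bin_size is not None and tolerance < bin_size:
        logger.warning(
            "tolerance %d < bin size %d: clusters will rarely merge", tolerance, bin_size
        )

    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for k, ts in enumerate(replicate_sets):
        for t in ts.tads:
            rep = t.replicate_id or f"rep{k}"
            per_chrom.setdefault(t.chrom, []).append((t.start, rep))
            per_chrom.setdefault(t.chrom, []).append((t.end, rep))

    consensus_tads: list[TAD] = []
    borders: list[tuple[str, int, int]] = []
    report: dict = {"chromosomes": {}, "tolerance": tolerance, "min_support": min_support}
    n_total = 0
    n_supported = 0
    for chrom in sorted(per_chrom):
        clusters = _cluster_positions(per_chrom[chrom], tolerance)
        chrom_boundaries = []
        cluster_info = []
        for cl in clusters:
            positions = [p for p, _ in cl]
            reps = {r for _, r in cl}
            supported = len(reps) >= min_support
            n_total += len(cl)
            if supported:
                n_supported += len(cl)
                pos = int(round(float(np.median(positions))))
                chrom_boundaries.append(pos)
                borders.append((chrom, min(positions), max(positions)))
            cluster_info.append(
                {
                    "positions": positions,
                    "replicates": sorted(reps),
                    "supported": supported,
                    "consensus_position": (
                        int(round(float(np.median(positions)))) if supported else None
                    ),
                }
            )
        for b0, b1 in zip(chrom_boundaries, chrom_boundaries[1:]):
            if b1 > b0:
                consensus_tads.append(TAD(chrom, b0, b1, "consensus"))
        report["chromosomes"][chrom] = {
            "consensus_boundaries": chrom_boundaries,
            "clusters": cluster_info,
        }

    frac = n_supported / n_total if n_total else float("nan")
    report["support_fraction"] = frac
    out = TADSet(tads=consensus_tads, borders=borders, consensus=True, support_fraction=frac)
    return out, report


def boundary_match(
    called: list[int], truth: list[int], tolerance: int = 20_000
) -> tuple[int, int]:
    """Evaluation helper: (number of truth boundaries with a called boundary
    within ``tolerance``, number of called boundaries matching no truth)."""
    called = sorted(called)
    truth = sorted(truth)
    recovered = sum(
        1 for t in truth if any(abs(c - t) <= tolerance for c in called)
    )
    spurious = sum(
        1 for c in called if not any(abs(c - t) <= tolerance for t in truth)
    )
    return recovered, spurious
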