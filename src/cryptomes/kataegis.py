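"""Kataegis detection by a negative-binomial cluster test.

Mutations within 10 bases collapse into single mutagenic events; runs of
events whose adjacent gaps are all under 10 kb form candidate clusters.
For a cluster with r+1 events spanning k unmutated bases in a genome
with per-base mutation probability p, the tail probability is the
negative-binomial CDF

    P = sum_{j=0..k} C(j+r-1, j) (1-p)^j p^r,

i.e. the chance of seeing at most k failures before the r-th success.
Clusters with Bonferroni-adjusted P < 1e-4 (family = candidate clusters
of the sample) are kataegis foci; clusters with identical member
positions shared by crypts of one patient are reported once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

EVENT_MERGE_BP = 10
CLUSTER_GAP_BP = 10_000
ADJUSTED_P_CUTOFF = 1e-4
MIN_CLUSTER_SPAN = 10
MAX_CLUSTER_SPAN = 10_000
#: default callable genome size for per-individual mutation rates
CALLABLE_GENOME = 2.9e9


def merge_events(positions: np.ndarray) -> list[list[int]]:
    """Collapse sorted positions within 10 bp into single events.

    Returns the member positions of each event; the event is anchored at
    its first position.
    """
    positions = np.asarray(positions)
    if len(positions) == 0:
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    events = [[int(positions[0])]]
    for pos in positions[1:]:
        if pos - events[-1][-1] <= EVENT_MERGE_BP:
            events[-1].append(int(pos))
        else:
            events.append([int(pos)])
    return events


def find_clusters(events: list[list[int]]) -> list[list[list[int]]]:
    """Maximal runs of >= 2 events with all adjacent gaps < 10 kb."""
    clusters, run = [], []
    for event in events:
        if run and event[0] - run[-1][0] >= CLUSTER_GAP_BP:
            if len(run) >= 2:
                clusters.append(run)
            run = []
        run.append(event)
    if len(run) >= 2:
        clusters.append(run)
    return clusters


def nb_pvalue(r: int, k: int, p: float) -> float:
    """Negative-binomial lower tail P(failures <= k before the r-th
    success), evaluated through the regularized incomplete beta function."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(special.betainc(r, k + 1, p))


@dataclass
class KataegisCluster:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    r: int
    k: int
    p: float
    p_raw: float
    p_adjusted: float
    members: tuple


def _split_overspan(cluster: list[list[int]]) -> list[list[list[int]]]:
    """Candidate groups must span 10..10,000 bp; a run wider than the cap
    (e.g. a dense cluster chaining a distant straggler) is split at its
    largest internal gap, recursively, keeping pieces with >= 2 events."""
    span = cluster[-1][-1] - cluster[0][0] + 1
    if span <= MAX_CLUSTER_SPAN:
        return [cluster]
    gaps = [cluster[i + 1][0] - cluster[i][-1] for i in range(len(cluster) - 1)]
    cut = int(np.argmax(gaps)) + 1
    out = []
    for part in (cluster[:cut], cluster[cut:]):
        if len(part) >= 2:
            out.extend(_split_overspan(part))
    return out


def _candidate_record(sample_id, chrom, cluster, p) -> KataegisCluster | None:
    members = tuple(pos for event in cluster for pos in event)
    start, end = members[0], members[-1]
    span = end - start + 1
    if not MIN_CLUSTER_SPAN <= span <= MAX_CLUSTER_SPAN:
        return None
    n_events = len(cluster)
    r = n_events - 1
    k = span - n_events  # unmutated bases spanned by the event group
    return KataegisCluster(
        sample_id, chrom, start, end, len(members), r, k, p,
        nb_pvalue(r, k, p), np.nan, members,
    )


def classify_clusters(
    mutations: pd.DataFrame,
    rate_per_base: float | dict,
    patient_of: dict | None = None,
) -> pd.DataFrame:
    """Full cluster scan over a table of passing substitutions.

    ``mutations`` needs sample_id/chrom/pos columns; ``rate_per_base`` is
    the per-individual mutation probability (scalar or sample_id -> rate).
    Bonferroni adjustment multiplies by the number of candidate clusters
    in the same sample; adjusted P < 1e-4 is kataegis.  Clusters with
    identical member positions in different crypts of the same patient
    are reported once (first sample in sort order).
    """
    out = []
    for (sample, chrom), grp in mutations.groupby(["sample_id", "chrom"], sort=True):
        p = rate_per_base[sample] if isinstance(rate_per_base, dict) else rate_per_base
        events = merge_events(np.sort(grp["pos"].values))
        for run in find_clusters(events):
            for cluster in _split_overspan(run):
                rec = _candidate_record(sample, chrom, cluster, p)
                if rec is not None:
                    out.append(rec)
    if not out:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "n_mutations",
                     "r", "k", "p", "p_raw", "p_adjusted", "members", "kataegis"]
        )
    df = pd.DataFrame([c.__dict__ for c in out])
    n_tests = df.groupby("sample_id")["p_raw"].transform("size")
    df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * n_tests)
    df["kataegis"] = df["p_adjusted"] < ADJUSTED_P_CUTOFF
    df = df.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
    if patient_of is not None:
        df["patient"] = df["sample_id"].map(patient_of)
        dup = df["kataegis"] & df.duplicated(subset=["patient", "chrom", "members"])
        df["duplicate_of_patient"] = dup
        df.loc[dup, "kataegis"] = False
    return df


def per_sample_rate(
    mutations: pd.DataFrame,
    patient_of: dict,
    callable_genome: float = CALLABLE_GENOME,
) -> dict:
    """Per-individual mutation probability: the patient's total passing
    substitutions divided by the callable genome length, shared by all of
    the patient's crypts."""
    counts = mutations.groupby(mutations["sample_id"].map(patient_of)).size()
    return {
        s: float(counts[patient_of[s]]) / callable_genome
        for s in mutations["sample_id"].unique()
    }


def rainfall(mutations: pd.DataFrame) -> pd.DataFrame:
    """Inter-mutation distances for rainfall plots.

    One row per mutation after the first of each (sample, chromosome),
    giving the distance to the previous mutation and the substitution
    class (pyrimidine strand) when ref/alt columns are present.
    """
    rows = []
    for (sample, chrom), grp in mutations.groupby(["sample_id", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].values
        if len(pos) < 2:
            continue
        dist = np.diff(pos)
        sub = None
        if "ref" in grp and "alt" in grp:
            comp = str.maketrans("ACGT", "TGCA")
            sub = [
                f"{r}>{a}" if r in "CT" else f"{r.translate(comp)}>{a.translate(comp)}"
                for r, a in zip(grp["ref"].values[1:], grp["alt"].values[1:])
            ]
        rows.append(pd.DataFrame(dict(
            sample_id=sample, chrom=chrom, pos=pos[1:], distance=dist,
            substitution=sub if sub is not None else "",
        )))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "chrom", "pos", "distance", "substitution"])
    return pd.concat(rows, ignore_index=True)
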