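"""96-channel spectra and EM signature attribution.

Attribution treats a mutation spectrum as a multinomial mixture of
reference signatures and estimates the mixing proportions by
expectation-maximization (deterministic from a uniform start).  The
threshold ladder used on crypt phylogenies is:

* two-round fit: signatures contributing <= 10% after a first EM round
  are dropped and the survivors re-fitted, to limit overfitting; the
  reconstruction must stay above 0.8 cosine similarity;
* per-individual permission: a signature is permitted for an individual
  only if it reaches a 5% share on at least one branch carrying more
  than 200 assigned mutations; final exposures are re-attributed within
  the permitted set;
* a crypt or branch is APOBEC-positive when SBS2 + SBS13 together reach
  at least 5% of its burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trinuc import CHANNELS, channel_of, trinuc_at

EM_TOL = 1e-8
EM_MAX_ITER = 10_000
PRUNE_SHARE = 0.10
PERMIT_SHARE = 0.05
PERMIT_BRANCH_LENGTH = 200
POSITIVE_SHARE = 0.05
RECONSTRUCTION_COSINE = 0.8
UBIQUITOUS = ("SBS1", "SBS5", "SBS18")
WES_GENOME_FACTOR = 50.0
APOBEC_SIGNATURES = ("SBS2", "SBS13")


def build_spectrum(mutations: pd.DataFrame, reference: dict[str, str]) -> pd.Series:
    """96-channel spectrum of single-base substitutions.

    ``mutations`` needs chrom/pos/ref/alt columns (1-based positions);
    reference alleles are checked against the sequence and purine-strand
    records are folded onto the pyrimidine strand.
    """
    counts = pd.Series(0, index=pd.Index(CHANNELS, name="channel"), dtype=int)
    mismatches = []
    for row in mutations.itertuples():
        seq = reference[row.chrom]
        base = seq[row.pos - 1].upper()
        if base != row.ref.upper():
            mismatches.append(f"{row.chrom}:{row.pos} ref {row.ref} != genome {base}")
            continue
        tri = trinuc_at(seq, row.pos)
        counts[channel_of(row.ref, row.alt, tri[0], tri[2])] += 1
    if mismatches:
        raise ValueError("reference mismatches: " + "; ".join(mismatches[:10]))
    return counts


def cosine(a, b) -> float:
    """Cosine similarity of two non-negative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class ExposureVector:
    """Per-signature attributed counts/proportions for one spectrum."""

    counts: pd.Series
    proportions: pd.Series
    total: float
    reconstruction_cosine: float
    loglik: float
    flags: list = field(default_factory=list)

    def share(self, names) -> float:
        names = [names] if isinstance(names, str) else list(names)
        return float(sum(self.proportions.get(n, 0.0) for n in names))


def _em(x: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, float]:
    """Multinomial-mixture EM from a uniform start; returns (pi, loglik).

    The per-iteration log-likelihood is non-decreasing by construction.
    """
    n_sig = S.shape[1]
    pi = np.full(n_sig, 1.0 / n_sig)
    last = -np.inf
    for _ in range(EM_MAX_ITER):
        mix = S @ pi  # per-channel probability
        mix = np.maximum(mix, 1e-300)
        ll = float(np.dot(x, np.log(mix)))
        # E-step responsibilities folded into the M-step update
        pi = pi * (S.T @ (x / mix))
        pi = np.maximum(pi, 0.0)
        pi /= pi.sum()
        if ll - last < EM_TOL * max(abs(ll), 1.0) and np.isfinite(last):
            last = ll
            break
        last = ll
    return pi, last


def em_attribute(spectrum: pd.Series, catalog: pd.DataFrame) -> ExposureVector:
    """EM attribution of a spectrum to a catalog subset."""
    if catalog.shape[1] < 1:
        raise ValueError("catalog must contain at least one signature")
    x = spectrum.reindex(CHANNELS).fillna(0).values.astype(float)
    total = x.sum()
    if total <= 0:
        raise ValueError("spectrum total must be positive")
    S = catalog.values.astype(float)
    flags = []
    # duplicate catalog entries make the split non-identifiable
    for i in range(S.shape[1]):
        for j in range(i + 1, S.shape[1]):
            if np.allclose(S[:, i], S[:, j]):
                flags.append(f"degenerate catalog: {catalog.columns[i]} == {catalog.columns[j]}")
    pi, ll = _em(x, S)
    counts = pd.Series(pi * total, index=catalog.columns)
    recon = S @ pi
    return ExposureVector(
        counts=counts,
        proportions=pd.Series(pi, index=catalog.columns),
        total=float(total),
        reconstruction_cosine=cosine(x, recon),
        loglik=ll,
        flags=flags,
    )


def two_round_prune(spectrum: pd.Series, catalog: pd.DataFrame) -> ExposureVector:
    """EM, drop signatures with <= 10% contribution, re-fit on survivors.

    Exposure counts always conserve the spectrum total.  A reconstruction
    cosine <= 0.8 is flagged but the exposures are still returned; if
    pruning removes everything the round-1 fit is returned with a flag.
    """
    round1 = em_attribute(spectrum, catalog)
    keep = round1.proportions.index[round1.proportions > PRUNE_SHARE]
    if len(keep) == 0:
        round1.flags.append("all signatures pruned; round-1 exposures returned")
        return round1
    result = em_attribute(spectrum, catalog[list(keep)])
    result.flags.extend(round1.flags)
    if result.reconstruction_cosine <= RECONSTRUCTION_COSINE:
        result.flags.append(
            f"reconstruction cosine {result.reconstruction_cosine:.3f} <= {RECONSTRUCTION_COSINE}"
        )
    return result


def permitted_signatures(
    branch_exposures: dict[int, ExposureVector],
    branch_lengths: dict[int, float],
    catalog: pd.DataFrame,
) -> tuple[set, list]:
    """Per-individual permitted signature set.

    A signature qualifies if it reaches a 5% share on at least one branch
    with more than 200 assigned mutations.  With no qualifying branch the
    ubiquitous set (SBS1/SBS5/SBS18) is permitted instead, flagged.
    """
    flags: list = []
    qualifying = [b for b, n in branch_lengths.items() if n > PERMIT_BRANCH_LENGTH]
    if not qualifying:
        allowed = {s for s in UBIQUITOUS if s in catalog.columns}
        flags.append("no branch with >200 mutations; ubiquitous signatures only")
        return allowed, flags
    allowed = set()
    for b in qualifying:
        exp = branch_exposures[b]
        for name, share in exp.proportions.items():
            if share >= PERMIT_SHARE:
                allowed.add(name)
    return allowed, flags


def finalize_exposures(
    spectra: dict[int, pd.Series],
    catalog: pd.DataFrame,
    allowed: set,
) -> dict[int, ExposureVector]:
    """Final per-branch attribution restricted to the permitted set; the
    reported signatures of a branch are those exceeding a 5% share."""
    allowed_cols = [c for c in catalog.columns if c in allowed]
    out = {}
    for b, spectrum in spectra.items():
        exp = em_attribute(spectrum, catalog[allowed_cols])
        exp.flags.append(
            "reported:" + ",".join(
                n for n, s in exp.proportions.items() if s > POSITIVE_SHARE
            )
        )
        out[b] = exp
    return out


def apobec_positive(exposure: ExposureVector) -> bool:
    """SBS2 + SBS13 share at least 5% of the burden."""
    return exposure.share(APOBEC_SIGNATURES) >= POSITIVE_SHARE


def scale_wes(apobec_count_exome: float) -> float:
    """Exome-to-genome scaling of APOBEC mutation counts (x50)."""
    return apobec_count_exome * WES_GENOME_FACTOR


def branch_proportion_test(table) -> dict:
    """Chi-squared test (with continuity correction) on a 2x2 table of
    APOBEC-positive vs -negative branch counts in two tissues.

    Returns the statistic, p-value, per-row positive proportions and
    their ratio; a warning flag is set when any expected cell is < 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 non-negative table")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=True)
    prop = t[:, 0] / t.sum(axis=1)
    return dict(
        statistic=float(chi2),
        p_value=float(p),
        proportions=(float(prop[0]), float(prop[1])),
        ratio=float(prop[0] / prop[1]) if prop[1] > 0 else np.inf,
        low_expected=bool((expected < 1).any()),
    )
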