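"""Extended sequence context of APOBEC mutations.

APOBEC3A- and APOBEC3B-like mutagenesis are distinguished by the base two
positions 5' of the mutated cytosine in TpCpA motifs: a pyrimidine (Y)
points to APOBEC3A-like activity, a purine (R) to APOBEC3B-like.
Enrichment compares the YTCA (RTCA) fraction among mutations against the
tetranucleotide content of the +/-20 bp sequence surrounding each
mutation, with Fisher exact tests in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .trinuc import revcomp

PYRIMIDINES = "CT"
PURINES = "AG"
BACKGROUND_FLANK = 20


@dataclass
class ContextTally:
    mut_ytca: int
    mut_rtca: int
    mut_c: int           # all pyrimidine-strand C>N mutations considered
    ctx_ytca: int
    ctx_rtca: int
    ctx_c: int           # background cytosines (both strands)

    @property
    def mut_tca(self) -> int:
        return self.mut_ytca + self.mut_rtca


def _pyrimidine_view(seq: str, pos: int, ref: str, alt: str):
    """(minus2, 5', 3') bases around a C>N mutation on the pyrimidine
    strand, or None if the site is not a C mutation / lacks context."""
    seq = seq.upper()
    ref, alt = ref.upper(), alt.upper()
    if ref == "C":
        if pos < 3 or pos > len(seq) - 1:
            return None
        return seq[pos - 3], seq[pos - 2], seq[pos]
    if ref == "G":
        if pos < 2 or pos > len(seq) - 2:
            return None
        # reverse complement: -2 on the pyrimidine strand is pos+2 forward
        return revcomp(seq[pos + 1]), revcomp(seq[pos]), revcomp(seq[pos - 2])
    return None


def classify_minus2(mutations: pd.DataFrame, reference: dict[str, str]) -> pd.DataFrame:
    """Label each TpCpA-context C mutation YTCA or RTCA by its -2 base.

    Non-C (pyrimidine strand) mutations and non-TCA contexts are excluded;
    returns a per-mutation table with the -2 base and the label.
    """
    rows = []
    for row in mutations.itertuples():
        view = _pyrimidine_view(reference[row.chrom], row.pos, row.ref, row.alt)
        if view is None:
            continue
        minus2, five, three = view
        if five != "T" or three != "A":
            continue
        label = "YTCA" if minus2 in PYRIMIDINES else "RTCA"
        rows.append(dict(chrom=row.chrom, pos=row.pos, ref=row.ref, alt=row.alt,
                         minus2=minus2, label=label))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "minus2", "label"])


def _window_context_counts(seq: str, pos: int, flank: int) -> tuple[int, int, int]:
    """(ytca, rtca, c) tetranucleotide/cytosine counts, both strands, in
    the +/-flank window around a 1-based position."""
    lo = max(0, pos - 1 - flank)
    hi = min(len(seq), pos + flank)
    win = seq[lo:hi].upper()
    ytca = rtca = 0
    c = win.count("C") + win.count("G")
    for strand in (win, revcomp(win)):
        for i in range(len(strand) - 3):
            if strand[i + 1 : i + 4] == "TCA":
                if strand[i] in PYRIMIDINES:
                    ytca += 1
                else:
                    rtca += 1
    return ytca, rtca, c


def tally_context(
    mutations: pd.DataFrame,
    reference: dict[str, str],
    flank: int = BACKGROUND_FLANK,
) -> ContextTally:
    """Mutation and matched-background context counts for enrichment."""
    labelled = classify_minus2(mutations, reference)
    mut_c = 0
    for row in mutations.itertuples():
        if row.ref.upper() in "CG":
            mut_c += 1
    ctx_y = ctx_r = ctx_c = 0
    for row in mutations.itertuples():
        if row.ref.upper() not in "CG":
            continue
        y, r, c = _window_context_counts(reference[row.chrom], row.pos, flank)
        ctx_y += y
        ctx_r += r
        ctx_c += c
    return ContextTally(
        mut_ytca=int((labelled["label"] == "YTCA").sum()),
        mut_rtca=int((labelled["label"] == "RTCA").sum()),
        mut_c=mut_c,
        ctx_ytca=ctx_y,
        ctx_rtca=ctx_r,
        ctx_c=ctx_c,
    )


def enrichment(tally: ContextTally) -> dict:
    """Enrichment scores and Fisher exact tests for YTCA and RTCA.

    enrichment(YTCA) = (mut_YTCA * ctx_C) / (mut_C * ctx_YTCA) over the
    matched background window; the Fisher test compares the YTCA:RTCA
    split among mutations to the background context counts, one-sided in
    each direction.
    """
    if tally.ctx_ytca == 0 or tally.ctx_rtca == 0 or tally.ctx_c == 0:
        raise ValueError("zero background context counts; cannot form enrichment")
    if tally.mut_c == 0:
        raise ValueError("no C mutations to test")
    e_ytca = (tally.mut_ytca * tally.ctx_c) / (tally.mut_c * tally.ctx_ytca)
    e_rtca = (tally.mut_rtca * tally.ctx_c) / (tally.mut_c * tally.ctx_rtca)
    table = [[tally.mut_ytca, tally.mut_rtca], [tally.ctx_ytca, tally.ctx_rtca]]
    p_ytca = stats.fisher_exact(table, alternative="greater")[1]
    p_rtca = stats.fisher_exact(table, alternative="less")[1]
    return dict(
        enrichment_ytca=float(e_ytca),
        enrichment_rtca=float(e_rtca),
        fisher_p_ytca=float(p_ytca),
        fisher_p_rtca=float(p_rtca),
        table=table,
    )


def extended_spectrum(
    mutations: pd.DataFrame,
    reference: dict[str, str],
    flank: int = 2,
) -> pd.DataFrame:
    """Per-position base frequencies around mutated C sites (pyrimidine
    strand), rows indexed by offset -flank..+flank, columns ACGT; each row
    sums to 1.  Suitable for sequence-logo rendering."""
    if len(mutations) == 0:
        raise ValueError("no mutations supplied")
    offsets = range(-flank, flank + 1)
    counts = {off: {b: 0 for b in "ACGT"} for off in offsets}
    n_used = 0
    for row in mutations.itertuples():
        seq = reference[row.chrom].upper()
        ref = row.ref.upper()
        if ref not in "CG":
            continue
        idx = row.pos - 1
        if idx - flank < 0 or idx + flank >= len(seq):
            continue
        window = seq[idx - flank : idx + flank + 1]
        if ref == "G":
            window = revcomp(window)
        for off, base in zip(offsets, window):
            if base in "ACGT":
                counts[off][base] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable C mutations with complete context")
    mat = pd.DataFrame(counts).T[list("ACGT")]
    mat.index.name = "offset"
    return mat.div(mat.sum(axis=1), axis=0)
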