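"""Tissue-specific exon sets and their sequence analyses: protein-domain
overlap, splice-site positional composition tests, polypyrimidine profiling,
and PWM motif enrichment in acceptor-side windows.

Acceptor windows are the ``window`` nucleotides 5' of the exon start in
transcription orientation (positions -window..-1); donor windows are the
``window`` nucleotides 3' of the exon end (+1..+window).  Positional tests
are Fisher 2x2 per (position, nucleotide), BH-corrected across positions
within each (side, nucleotide) family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DomainRecord, ExonRecord, Genome, PWM, TranscriptAnnotation, extract_window
from .stats import bh_adjust, fisher_2x2, fisher_2x2_ci, fisher_one_sided_greater

BASES = "ACGT"


@dataclass
class ExonSetPair:
    comparison: str
    set1: list[str]
    label1: str
    set2: list[str]
    label2: str

    def __post_init__(self):
        if set(self.set1) & set(self.set2):
            raise ValueError("exon sets must be disjoint")


def derive_specific_exons(specific1: list[str], specific2: list[str],
                          ann: TranscriptAnnotation,
                          label1: str = "tissue1", label2: str = "tissue2"
                          ) -> ExonSetPair:
    """Exons private to each tissue's specific isoforms.

    Only genes contributing at least one specific isoform on BOTH sides are
    used; within those genes, set1 = exons of tissue1-specific isoforms not
    present in any tissue2-specific isoform of the same comparison, and
    symmetrically for set2.
    """
    g1 = {ann.gene_of(t) for t in specific1}
    g2 = {ann.gene_of(t) for t in specific2}
    both = g1 & g2
    iso1 = [t for t in specific1 if ann.gene_of(t) in both]
    iso2 = [t for t in specific2 if ann.gene_of(t) in both]
    e1 = ann.exon_ids_of_transcripts(iso1)
    e2 = ann.exon_ids_of_transcripts(iso2)
    return ExonSetPair(f"{label1}_vs_{label2}", sorted(e1 - e2), label1,
                       sorted(e2 - e1), label2)


def first_exons(ann: TranscriptAnnotation) -> set[str]:
    """The 5'-most exon of every isoform (excluded from motif analysis)."""
    return {exons[0] for exons in ann.transcripts.values() if exons}


# ---------------------------------------------------------------------------
# protein-domain overlap
# ---------------------------------------------------------------------------

def _exon_lookup(ann) -> dict[str, ExonRecord]:
    return ann.exons if isinstance(ann, TranscriptAnnotation) else dict(ann)


def domain_overlap_test(pair: ExonSetPair, ann, domains: list[DomainRecord]):
    """Fisher 2x2 of (set1 vs set2) x (>=1 bp domain overlap); strand-blind."""
    exons = _exon_lookup(ann)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    for ivs in by_chrom.values():
        ivs.sort()

    def overlaps(ex: ExonRecord) -> bool:
        import bisect
        ivs = by_chrom.get(ex.chrom, [])
        i = bisect.bisect_left(ivs, (ex.end, ex.end))
        # any interval starting before exon end may reach into it
        for s, e in ivs[max(0, i - len(ivs)):i]:
            if e > ex.start:
                return True
        return False

    flags1 = {e: overlaps(exons[e]) for e in pair.set1}
    flags2 = {e: overlaps(exons[e]) for e in pair.set2}
    if not flags1 or not flags2:
        return {"skipped": True, "flags1": flags1, "flags2": flags2}
    a, b = sum(flags1.values()), len(flags1) - sum(flags1.values())
    c, d = sum(flags2.values()), len(flags2) - sum(flags2.values())
    or_, ci, p = fisher_2x2_ci((a, b, c, d))
    return {"skipped": False, "flags1": flags1, "flags2": flags2,
            "table": (a, b, c, d), "odds_ratio": or_, "ci": ci, "p": p}


# ---------------------------------------------------------------------------
# splice-site profiles and positional tests
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteProfile:
    """Per-position base counts for one exon set and one side.

    ``counts`` is (window x 4) over (A, C, G, T); ``positions`` carries the
    biological indexing (acceptor -window..-1, donor +1..+window).
    ``n_contributing`` gives the number of untruncated windows per position.
    """

    side: str
    counts: np.ndarray
    positions: np.ndarray
    n_contributing: np.ndarray


def _window_sequences(exon_ids, exons, genome: Genome, side: str, window: int):
    seqs = []
    for eid in exon_ids:
        ex = exons[eid]
        if ex.chrom not in genome:
            warnings.warn(f"exon {eid!r} on missing chromosome {ex.chrom!r}; skipped")
            continue
        anchor = ex.start if (side == "acceptor") == (ex.strand == "+") else ex.end
        wside = "up" if side == "acceptor" else "down"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq, truncated = extract_window(genome, ex.chrom, anchor, window,
                                            wside, ex.strand)
        seqs.append((seq, truncated))
    return seqs


def _profile(exon_ids, exons, genome, side, window) -> SpliceSiteProfile:
    counts = np.zeros((window, 4), dtype=int)
    n_contrib = np.zeros(window, dtype=int)
    for seq, truncated in _window_sequences(exon_ids, exons, genome, side, window):
        if truncated:
            # align what remains: truncated windows drop positions, not pad
            offset = window - len(seq)
        else:
            offset = 0
        for j, base in enumerate(seq):
            k = BASES.find(base)
            if k >= 0:
                counts[offset + j, k] += 1
                n_contrib[offset + j] += 1
    positions = (np.arange(-window, 0) if side == "acceptor"
                 else np.arange(1, window + 1))
    return SpliceSiteProfile(side, counts, positions, n_contrib)


def splice_profiles(pair: ExonSetPair, ann, genome: Genome,
                    window: int = 100) -> dict[str, dict[str, SpliceSiteProfile]]:
    """Acceptor and donor base-composition profiles for both exon sets."""
    exons = _exon_lookup(ann)
    return {
        label: {side: _profile(ids, exons, genome, side, window)
                for side in ("acceptor", "donor")}
        for label, ids in ((pair.label1, pair.set1), (pair.label2, pair.set2))
    }


def positional_tests(profiles: dict[str, dict[str, SpliceSiteProfile]],
                     sides=("acceptor", "donor"),
                     ci: bool = True) -> pd.DataFrame:
    """Per (side, position, nucleotide), Fisher 2x2 of set x is-nucleotide.

    BH adjustment runs across positions within each (side, nucleotide)
    family.  Zero-margin tables report OR = NaN, p = 1.  With ``ci=False``
    the exact confidence interval and conditional-MLE OR are skipped (the
    sample odds ratio is reported instead) -- the p-values are identical;
    use this in large simulation sweeps.
    """
    (label1, label2) = list(profiles)
    rows = []
    for side in sides:
        p1, p2 = profiles[label1][side], profiles[label2][side]
        for i, pos in enumerate(p1.positions):
            for k, base in enumerate(BASES):
                a = int(p1.counts[i, k]); b = int(p1.n_contributing[i]) - a
                c = int(p2.counts[i, k]); d = int(p2.n_contributing[i]) - c
                if ci:
                    or_, (lo, hi), p = fisher_2x2_ci((a, b, c, d))
                else:
                    from scipy.stats import fisher_exact
                    if min(a + b, c + d, a + c, b + d) == 0:
                        or_, p = float("nan"), 1.0
                    else:
                        p = float(fisher_exact([[a, b], [c, d]])[1])
                        or_ = (a * d) / (b * c) if b * c > 0 else float("inf")
                    lo = hi = float("nan")
                rows.append((side, int(pos), base, a, b, c, d, or_,
                             lo, hi, p))
    out = pd.DataFrame(rows, columns=["side", "position", "nucleotide",
                                      "a", "b", "c", "d", "odds_ratio",
                                      "ci_low", "ci_high", "p"])
    out["p_adj"] = np.nan
    for (_s, _b), idx in out.groupby(["side", "nucleotide"]).groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    # flag the most common nucleotide at each position (display convention)
    tot = out.groupby(["side", "position", "nucleotide"])[["a", "c"]].sum().sum(axis=1)
    top = tot.groupby(level=[0, 1]).idxmax()
    top_keys = set(top.to_list())
    out["most_common"] = [
        (s, p, b) in top_keys for s, p, b in zip(out["side"], out["position"],
                                                 out["nucleotide"])]
    return out


def polypyrimidine_profile(profiles) -> dict:
    """Pyrimidine and thymine fractions per acceptor position, plus the
    thymine positional Fisher tests (BH across positions)."""
    (label1, label2) = list(profiles)
    frac = {}
    for label in (label1, label2):
        prof = profiles[label]["acceptor"]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = prof.counts[:, BASES.index("T")] / prof.n_contributing
            c = prof.counts[:, BASES.index("C")] / prof.n_contributing
        frac[label] = pd.DataFrame({"position": prof.positions,
                                    "t_fraction": t, "c_fraction": c,
                                    "pyrimidine_fraction": t + c})
    tests = positional_tests(profiles, sides=("acceptor",))
    t_tests = tests[tests["nucleotide"] == "T"].reset_index(drop=True)
    sig = t_tests[t_tests["p_adj"] < 0.05]
    summary = {
        f"n_sig_{label1}": int((sig["odds_ratio"] > 1).sum()),
        f"n_sig_{label2}": int((sig["odds_ratio"] < 1).sum()),
    }
    return {"fractions": frac, "t_tests": t_tests, "summary": summary}


# ---------------------------------------------------------------------------
# PWM motif enrichment in acceptor-side windows
# ---------------------------------------------------------------------------

def pwm_max_score(seq: str, pwm: PWM) -> float:
    """Best log-odds score of the PWM (vs uniform background) over all sense
    positions of ``seq``; -inf if the sequence is shorter than the motif."""
    L = len(pwm)
    if len(seq) < L:
        return float("-inf")
    logodds = np.log2(np.maximum(pwm.columns, 1e-9) / 0.25)
    idx = np.full(len(seq), -1)
    for k, b in enumerate(BASES):
        for i, ch in enumerate(seq):
            if ch == b:
                idx[i] = k
    best = float("-inf")
    for start in range(len(seq) - L + 1):
        window = idx[start:start + L]
        if (window < 0).any():
            continue
        best = max(best, float(logodds[np.arange(L), window].sum()))
    return best


def _contains(seqs: list[str], pwm: PWM, frac_of_max: float) -> np.ndarray:
    thresh = frac_of_max * float(np.log2(np.maximum(pwm.columns, 1e-9) / 0.25).max(axis=1).sum())
    return np.array([pwm_max_score(s, pwm) >= thresh for s in seqs])


def motif_window_enrichment(pair: ExonSetPair, ann, genome: Genome,
                            pwms: list[PWM], window: int = 100,
                            exclude: set[str] | None = None,
                            frac_of_max: float = 0.8) -> pd.DataFrame:
    """Differential motif occurrence in acceptor-side upstream windows.

    A window "contains" a motif when the best sense-strand log-odds score
    (uniform background) reaches ``frac_of_max`` of the maximum attainable
    score.  Per motif, one-sided Fisher tests run in both directions (set1
    enriched / set2 enriched), BH over motifs per direction; the direction
    with the smaller q is kept and the log2 ratio of containment proportions
    is signed positive for set1 enrichment.  First exons of every isoform
    should be excluded via ``exclude``.
    """
    exons = _exon_lookup(ann)
    excl = exclude or set()
    ids1 = [e for e in pair.set1 if e not in excl]
    ids2 = [e for e in pair.set2 if e not in excl]
    seqs1 = [s for s, _t in _window_sequences(ids1, exons, genome, "acceptor", window)]
    seqs2 = [s for s, _t in _window_sequences(ids2, exons, genome, "acceptor", window)]
    rows = []
    for pwm in pwms:
        if len(pwm) > window:
            warnings.warn(f"PWM {pwm.motif_id!r} longer than window; skipped")
            continue
        h1 = _contains(seqs1, pwm, frac_of_max)
        h2 = _contains(seqs2, pwm, frac_of_max)
        a, b = int(h1.sum()), int(len(h1) - h1.sum())
        c, d = int(h2.sum()), int(len(h2) - h2.sum())
        p_set1 = fisher_one_sided_greater((a, b, c, d))
        p_set2 = fisher_one_sided_greater((c, d, a, b))
        prop1 = a / max(len(h1), 1)
        prop2 = c / max(len(h2), 1)
        eps = 0.5 / max(len(h1), 1), 0.5 / max(len(h2), 1)
        lr = float(np.log2((prop1 + eps[0]) / (prop2 + eps[1])))
        rows.append((pwm.motif_id, pwm.rbp_name, a, len(h1), c, len(h2),
                     prop1, prop2, lr, p_set1, p_set2))
    out = pd.DataFrame(rows, columns=["motif_id", "rbp_name", "hits1", "n1",
                                      "hits2", "n2", "prop1", "prop2",
                                      "log2_ratio", "p_set1", "p_set2"])
    if not len(out):
        return out.assign(q=[], favored=[], p=[])
    q1 = bh_adjust(out["p_set1"].to_numpy())
    q2 = bh_adjust(out["p_set2"].to_numpy())
    pick1 = q1 <= q2
    out["favored"] = np.where(pick1, pair.label1, pair.label2)
    out["p"] = np.where(pick1, out["p_set1"], out["p_set2"])
    out["q"] = np.where(pick1, q1, q2)
    return out
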