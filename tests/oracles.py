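"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive (per-base loops, all-pairs scans,
O(m^2) procedures) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

# -- consensus ---------------------------------------------------------------


def brute_consensus(caller_peak_lists, chrom_lengths, min_support=2, min_length=150):
    """Per-base recomputation of the 'sum >= min_support, length >= min_length'
    rule. caller_peak_lists: per caller, list of (chrom, start, end)."""
    regions = []
    for chrom, L in chrom_lengths.items():
        summed = [0] * L
        for peaks in caller_peak_lists:
            occupied = [0] * L
            for c, s, e in peaks:
                if c != chrom:
                    continue
                for pos in range(s, e):
                    occupied[pos] = 1
            for pos in range(L):
                summed[pos] += occupied[pos]
        run_start = None
        for pos in range(L + 1):
            above = pos < L and summed[pos] >= min_support
            if above and run_start is None:
                run_start = pos
            elif not above and run_start is not None:
                if pos - run_start >= min_length:
                    regions.append((chrom, run_start, pos))
                run_start = None
    return regions


def naive_bh(p_values):
    """Step-up Benjamini-Hochberg, O(m^2), straight from the definition."""
    m = len(p_values)
    q = []
    for p_i in p_values:
        rank_i = sum(1 for p_j in p_values if p_j <= p_i)
        # q_i = min over p_j >= p_i of m * p_j / rank_j
        best = 1.0
        for p_j in p_values:
            if p_j >= p_i:
                rank_j = sum(1 for p_k in p_values if p_k <= p_j)
                best = min(best, m * p_j / rank_j)
        q.append(min(1.0, best))
    return q


def poisson_upper_tail(observed, lam):
    """P(X >= observed) for Poisson(lam), summing the tail pmf upward
    (avoids the cancellation of 1 - cdf for small tails)."""
    if observed <= 0:
        return 1.0
    # pmf at `observed` via logs to dodge overflow, then recurrence upward
    log_term = -lam + observed * math.log(lam) - math.lgamma(observed + 1)
    term = math.exp(log_term)
    total = 0.0
    k = observed
    while term > 0 and (term / max(total, 1e-300) > 1e-17 or k < observed + 10):
        total += term
        k += 1
        term *= lam / k
    return total


# -- motif -------------------------------------------------------------------

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}


def _oracle_rc(s):
    return "".join(_ORACLE_COMP[c] for c in reversed(s.upper()))


def naive_scan(seq, left, smin, smax, right, both_strands=True):
    """Enumerate every offset x spacer x strand and check base by base.

    Returns a set of (offset, length, spacer, strand) tuples in forward
    coordinates.
    """
    seq = seq.upper()
    hits = set()
    variants = [("+", left, right)]
    if both_strands:
        variants.append(("-", _oracle_rc(right), _oracle_rc(left)))
    for strand, lpart, rpart in variants:
        for spacer in range(smin, smax + 1):
            pattern = lpart + "N" * spacer + rpart
            for off in range(len(seq) - len(pattern) + 1):
                ok = True
                for j, code in enumerate(pattern):
                    if seq[off + j] not in _ORACLE_IUPAC[code]:
                        ok = False
                        break
                if ok:
                    hits.add((off, len(pattern), spacer, strand))
    return hits


# -- annotation --------------------------------------------------------------


def brute_nearest_gene(site_centers, genes, max_distance=1_000_000):
    """All-pairs nearest-TSS assignment.

    site_centers: list of (chrom, center). genes: list of
    (gene_id, chrom, tss). Returns list of (gene_id or None, |distance|),
    ties broken by smaller TSS then lexicographic gene id.
    """
    out = []
    for chrom, center in site_centers:
        best = None
        for gene_id, gchrom, tss in genes:
            if gchrom != chrom:
                continue
            key = (abs(center - tss), tss, gene_id)
            if best is None or key < best:
                best = key
        if best is None or best[0] > max_distance:
            out.append((None, None))
        else:
            out.append((best[2], best[0]))
    return out
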