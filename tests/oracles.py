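"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the package's classifier code paths: anchored
classification walks genomic positions one base at a time, and isoform
qualification enumerates every substring of the enlarged locus window into a
set before membership testing.
"""

from __future__ import annotations

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _read_base_positions(ann, read_len):
    """Genomic (position, complemented?) pairs covered by an anchored read,
    in read orientation."""
    if ann.strand == "+":
        return [(ann.start + i, False) for i in range(read_len)]
    return [(ann.end - 1 - i, True) for i in range(read_len)]


def brute_classify_anchored(read, ann, genome, max_mm=0):
    """Position-by-position anchored classification on the genome."""
    L = len(read)
    if L < 18 or L > 26:
        return "unanchored"
    mismatches = 0
    for i, (pos, comp) in enumerate(_read_base_positions(ann, L)):
        if i >= ann.length:  # beyond the annotated 3' end: free
            break
        if pos < 0 or pos >= len(genome):  # off the genome: not comparable
            continue
        base = genome[pos]
        if comp:
            base = _COMP[base]
        if read[i] != base:
            mismatches += 1
    if mismatches > max_mm:
        return "unanchored"
    if read == ann.mature_seq:
        return "exact"
    if L < ann.length:
        return "shorter"
    if L > ann.length:
        return "longer"
    return "anomalous"


def brute_anchored_counts(collapsed, ref, max_mm=0, max_loci=500):
    """Per-locus anchored class counts via the brute-force classifier.

    Returns {mirna_id: Counter(class -> count)}.
    """
    out = {a.id: Counter() for a in ref.annotations}
    for cr in collapsed:
        hits = []
        for ann in ref.annotations:
            cls = brute_classify_anchored(cr.sequence, ann, ref.genome, max_mm)
            if cls != "unanchored":
                hits.append((ann.id, cls))
        if not hits or len(hits) > max_loci:
            continue
        for ann_id, cls in hits:
            out[ann_id][cls] += cr.count
    return out


def enumerate_nested_substrings(ref, ann, flank=5, len_tol=1):
    """All perfectly templated strings nested in the enlarged locus window
    with length within len_tol of the mature length."""
    lo = max(0, ann.start - flank)
    hi = min(len(ref.genome), ann.end + flank)
    window = ref.genome[lo:hi]
    if ann.strand == "-":
        window = "".join(_COMP[b] for b in reversed(window))
    allowed = set()
    for L in range(ann.length - len_tol, ann.length + len_tol + 1):
        for i in range(len(window) - L + 1):
            allowed.add(window[i : i + L])
    return allowed


def brute_isoform_counts(collapsed, ref):
    """{mirna_id: (n_qualifying, n_exact)} via substring-set enumeration."""
    out = {}
    for ann in ref.annotations:
        allowed = enumerate_nested_substrings(ref, ann)
        n_qual = n_exact = 0
        for cr in collapsed:
            if cr.sequence in allowed:
                n_qual += cr.count
                if cr.sequence == ann.mature_seq:
                    n_exact += cr.count
        out[ann.id] = (n_qual, n_exact)
    return out


def welch_or_student_t(a, b, equal_var):
    """Closed-form two-sample t statistic and two-sided p-value, coded from
    the textbook formulas (independent of scipy.stats.ttest_ind)."""
    import math

    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2 * t_dist.sf(abs(t), df)
    return t, p
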