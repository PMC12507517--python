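"""Independent brute-force reference implementations used by the tests.

Deliberately written from first principles (no imports from kbsites) so they
check, rather than mirror, the library code paths.
"""

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "N": "ACGT",
}


def brute_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_mismatches(kmer, consensus):
    return sum(1 for b, s in zip(kmer, consensus) if b not in _IUPAC[s])


def brute_force_sites(
    sequence,
    entries,
    consensus="GGGRNNYYCC",
    max_mismatches=3,
    both_strands=True,
    strong_threshold=6.0,
):
    """Enumerate every window on both strands; apply membership, positivity,
    mismatch and strand-collapse rules.  Returns tuples
    (start, strand, kmer, z, mismatches, site_class)."""
    seq = sequence.upper()
    out = []
    for start in range(len(seq) - 9):
        window = seq[start : start + 10]
        if any(b not in "ACGT" for b in window):
            continue
        candidates = []
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            kmer = window if strand == "+" else brute_revcomp(window)
            z = entries.get(kmer)
            if z is None or z <= 0:
                continue
            if brute_mismatches(kmer, consensus) > max_mismatches:
                continue
            candidates.append((strand, kmer, z))
        if not candidates:
            continue
        best = candidates[0]
        if len(candidates) == 2 and candidates[1][2] > candidates[0][2]:
            best = candidates[1]
        strand, kmer, z = best
        out.append(
            (
                start,
                strand,
                kmer,
                z,
                brute_mismatches(kmer, consensus),
                "strong" if z >= strong_threshold else "weak",
            )
        )
    return out


def brute_pearson(x, y):
    """Textbook Pearson correlation from sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def brute_enriched(counts, exp_cols, ctl_cols, min_total=5, z_margin=0.5):
    """Re-run the whole enrichment pipeline with plain loops.

    ``counts``: dict protein -> dict label -> count.  Returns the set of
    passing proteins.
    """
    labels = exp_cols + ctl_cols
    kept = [p for p, row in counts.items() if sum(row[l] for l in labels) >= min_total]
    col_tot = {l: sum(counts[p][l] for p in kept) for l in labels}
    norm = {p: {l: counts[p][l] / col_tot[l] for l in labels} for p in kept}
    passing = set()
    for p in kept:
        vals = [norm[p][l] for l in labels]
        m = sum(vals) / len(vals)
        var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        if var == 0:
            z = {l: 0.0 for l in labels}
        else:
            sd = var ** 0.5
            z = {l: (norm[p][l] - m) / sd for l in labels}
        score = sum(z[l] for l in exp_cols) / len(exp_cols) - sum(
            z[l] for l in ctl_cols
        ) / len(ctl_cols)
        if score > z_margin:
            passing.add(p)
    return passing


def brute_best_partition(rows, k):
    """Exhaustive minimum-WCSS partition of <= 12 rows into k clusters."""
    n = len(rows)
    best_labels, best_wcss = None, float("inf")
    for assignment in product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        wcss = 0.0
        for c in range(k):
            members = [rows[i] for i in range(n) if assignment[i] == c]
            dim = len(members[0])
            centroid = [sum(m[d] for m in members) / len(members) for d in range(dim)]
            wcss += sum(
                sum((m[d] - centroid[d]) ** 2 for d in range(dim)) for m in members
            )
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, assignment
    return best_labels, best_wcss
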