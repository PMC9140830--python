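"""Independent from-definition oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation, nested loops — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def pearson_oracle(x, y) -> float:
    """Pearson r by direct summation of the product-moment definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _rank_with_ties(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_oracle(groups: dict) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank-sum definition."""
    labels = []
    values = []
    for name, arr in groups.items():
        for v in arr:
            labels.append(name)
            values.append(float(v))
    n = len(values)
    ranks = _rank_with_ties(values)
    h = 0.0
    for name in groups:
        r = [ranks[i] for i in range(n) if labels[i] == name]
        h += (sum(r) ** 2) / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = Counter(values)
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def dunn_oracle(groups: dict) -> dict:
    """Dunn z and two-sided p per pair, from the pooled-rank definition."""
    from scipy.stats import norm

    labels = []
    values = []
    for name, arr in groups.items():
        for v in arr:
            labels.append(name)
            values.append(float(v))
    n = len(values)
    ranks = _rank_with_ties(values)
    mean_rank = {}
    sizes = {}
    for name in groups:
        r = [ranks[i] for i in range(n) if labels[i] == name]
        mean_rank[name] = sum(r) / len(r)
        sizes[name] = len(r)
    ties = Counter(values)
    tie_term = sum(t**3 - t for t in ties.values())
    out = {}
    for a, b in itertools.combinations(groups, 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = (z, min(1.0, 2.0 * norm.sf(abs(z))))
    return out


def holm_oracle(pvalues):
    """Holm step-down adjustment by its textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvalues[i])
        adj[i] = min(1.0, running)
    return adj


def hypergeom_tail_oracle(n_universe: int, n_marked: int, n_draw: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all draws (small N only)."""
    universe = list(range(n_universe))
    marked = set(universe[:n_marked])
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n_draw):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def pwm_tail_oracle(scaled: np.ndarray, background, scaled_score: int) -> float:
    """P(discretized word score >= s) by enumerating all 4^w words."""
    width = scaled.shape[0]
    p = 0.0
    for word in itertools.product(range(4), repeat=width):
        s = sum(int(scaled[i, c]) for i, c in enumerate(word))
        if s >= scaled_score:
            q = 1.0
            for c in word:
                q *= background[c]
            p += q
    return p


def naive_scan_oracle(sequence, pwm, p_threshold, granularity=1e-3):
    """All-window rescan using the DP tail but a per-window python loop.

    Returns a set of (start, scaled_score) for windows with p < threshold.
    """
    from syndriver.motif_scan import encode_sequence, log_odds_matrix, score_pvalues

    lom = log_odds_matrix(pwm)
    dist = score_pvalues(lom, pwm.background, granularity)
    codes = encode_sequence(sequence.upper().replace("U", "T"))
    out = set()
    w = pwm.width
    for start in range(len(sequence) - w + 1):
        window = codes[start : start + w]
        if min(window) < 0:
            continue
        s = sum(int(dist.scaled[i, window[i]]) for i in range(w))
        if dist.pvalue(s) < p_threshold:
            out.add((start + 1, s))
    return out


def driver_filter_oracle(variants, tau_effect, tau_cons, cancer_genes):
    """Brute-force re-derivation of the proposed-driver key set."""
    patients = {}
    for v in variants:
        patients.setdefault(v.key, set()).add(v.patient_id)
    proposed = set()
    for v in variants:
        eff = v.scores.get("effect_score")
        gerp = v.scores.get("gerp")
        if eff is None or gerp is None:
            continue
        if (
            eff > tau_effect
            and gerp > tau_cons
            and v.gene in cancer_genes
            and len(patients[v.key]) >= 2
        ):
            proposed.add(v.key)
    return proposed


def gene_group_oracle(variants, tau_effect, tau_cons):
    """Brute-force per-gene group label from the cumulative filter definition."""
    syn = [v for v in variants if v.consequence == "synonymous"]
    patients = {}
    for v in syn:
        patients.setdefault(v.key, set()).add(v.patient_id)
    groups = {}
    for v in syn:
        rec = len(patients[v.key]) >= 2
        cons = v.scores.get("gerp")
        eff = v.scores.get("effect_score")
        level = 1
        if rec:
            level = 2
            if cons is not None and cons > tau_cons:
                level = 3
                if eff is not None and eff > tau_effect:
                    level = 4
        groups[v.gene] = max(groups.get(v.gene, 1), level)
    return groups


def venn_oracle(triples):
    """Region counts by direct set algebra over (splicing, structure, rbp) flags."""
    s = {k for k, (a, _, _) in triples.items() if a}
    t = {k for k, (_, b, _) in triples.items() if b}
    r = {k for k, (_, _, c) in triples.items() if c}
    return {
        "splicing_only": len(s - t - r),
        "structure_only": len(t - s - r),
        "rbp_only": len(r - s - t),
        "splicing_structure": len((s & t) - r),
        "splicing_rbp": len((s & r) - t),
        "structure_rbp": len((t & r) - s),
        "all_three": len(s & t & r),
        "union": len(s | t | r),
    }
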