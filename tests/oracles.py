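"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately written against Biopython's translation
table and plain Python loops, not against the package's own code paths, so
agreement is meaningful.
"""

import functools
import itertools
import math

from Bio.Seq import Seq

NUCS = "ACGT"


@functools.lru_cache(maxsize=None)
def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def ng86_sites_oracle(seq: str) -> tuple[float, float]:
    """Exhaustive scan of all nine single-nucleotide neighbours per codon."""
    s = n = 0.0
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if is_stop(codon):
            continue
        for k in range(3):
            syn = 0
            for b in NUCS:
                if b == codon[k]:
                    continue
                mut = codon[:k] + b + codon[k + 1 :]
                if not is_stop(mut) and translate(mut) == translate(codon):
                    syn += 1
            s += syn / 3
            n += (3 - syn) / 3
    return s, n


def pathway_nd_sd_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Average (Nd, Sd) over all orderings of the changes; orderings that
    pass through a stop codon are dropped (all kept if none is stop-free),
    mirroring standard NG86 multi-hit handling."""
    diff = [k for k in range(3) if ca[k] != cb[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, nd, sd, stop = ca, 0, 0, False
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1 :]
            stop = stop or is_stop(nxt)
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((nd, sd, stop))
    keep = [(nd, sd) for nd, sd, stop in paths if not stop]
    if not keep:
        keep = [(nd, sd) for nd, sd, _ in paths]
    return (sum(p[0] for p in keep) / len(keep),
            sum(p[1] for p in keep) / len(keep))


def dnds_oracle(seq_a: str, seq_b: str):
    """(Nd, Sd, dN, dS) for a codon-aligned pair without internal stops."""
    sa, na = ng86_sites_oracle(seq_a)
    sb, nb = ng86_sites_oracle(seq_b)
    s_sites, n_sites = (sa + sb) / 2, (na + nb) / 2
    nd = sd = 0.0
    for i in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        if is_stop(ca) or is_stop(cb):
            continue
        d_nd, d_sd = pathway_nd_sd_oracle(ca, cb)
        nd += d_nd
        sd += d_sd
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return nd, sd, jc(nd / n_sites), jc(sd / s_sites)


def pairwise_pi_oracle(haplotypes: list[str], length: int) -> float:
    """Window pi as mean pairwise difference: sum_{i<j} d_ij / (C(n,2)*L)."""
    n = len(haplotypes)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(haplotypes[i], haplotypes[j]))
    return total / (n * (n - 1) / 2) / length


def bh_stepup_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
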