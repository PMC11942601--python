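"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with the library: the ROH scanner
enumerates every window and run with plain Python loops, the kinship oracle
is Wright's path-counting formula, and the incidence oracle is a quadratic
membership scan.
"""

from __future__ import annotations

from functools import lru_cache


def oracle_detect_roh(geno, pos, params):
    """Exhaustive window/run scan for one individual on one chromosome.

    Returns a list of (start_bp, end_bp, n_snps) tuples.
    """
    n = len(geno)
    w = params.window_snps
    eligible = [False] * n
    for j in range(n):
        total = hits = 0
        for s in range(max(0, j - w + 1), min(j, n - w) + 1):
            window = geno[s: s + w]
            n_het = sum(1 for g in window if g == 1)
            n_mis = sum(1 for g in window if g < 0)
            total += 1
            if n_het <= params.max_het_in_window and n_mis <= params.max_missing_in_window:
                hits += 1
        if total and hits / total >= params.window_hit_fraction:
            eligible[j] = True

    # maximal eligible runs, split at big gaps, then filter
    segments = []
    run = []
    for j in range(n + 1):
        if j < n and eligible[j]:
            run.append(j)
            continue
        if run:
            pieces = [[run[0]]]
            for k in run[1:]:
                if pos[k] - pos[pieces[-1][-1]] > params.max_gap_kb * 1000:
                    pieces.append([k])
                else:
                    pieces[-1].append(k)
            for piece in pieces:
                a, b = piece[0], piece[-1]
                while a <= b and geno[a] not in (0, 2):
                    a += 1
                while b >= a and geno[b] not in (0, 2):
                    b -= 1
                if b < a:
                    continue
                n_snps = b - a + 1
                length = pos[b] - pos[a] + 1
                if n_snps < params.min_snps_in_roh:
                    continue
                if length < params.min_length_kb * 1000:
                    continue
                if length / n_snps > params.min_density_kb_per_snp * 1000:
                    continue
                segments.append((int(pos[a]), int(pos[b]), n_snps))
        run = []
    return segments


def wright_path_inbreeding(parents: dict) -> dict:
    """Inbreeding coefficients by Wright's path-counting formula.

    ``parents`` maps id -> (sire or None, dam or None). For each individual,
    F = sum over common ancestors A and pairs of ancestor paths (sire side,
    dam side) that share only A, of (1/2)^(n1+n2+1) * (1 + F_A).
    """

    def paths_up(x):
        """All ancestor paths from x: list of (ancestor, frozenset(nodes), length)."""
        out = [(x, frozenset([x]), 0)]
        s, d = parents.get(x, (None, None))
        for p in (s, d):
            if p is not None:
                for anc, nodes, ln in paths_up(p):
                    out.append((anc, nodes | {x}, ln + 1))
        return out

    @lru_cache(maxsize=None)
    def F(x):
        s, d = parents.get(x, (None, None))
        if s is None or d is None:
            return 0.0
        total = 0.0
        for anc1, nodes1, l1 in paths_up(s):
            for anc2, nodes2, l2 in paths_up(d):
                if anc1 != anc2:
                    continue
                if nodes1 & nodes2 != {anc1}:
                    continue
                total += 0.5 ** (l1 + l2 + 1) * (1.0 + F(anc1))
        return total

    return {x: F(x) for x in parents}


def oracle_incidence(segments, chroms, positions, samples):
    """Quadratic per-SNP membership count over (individual, segment) pairs."""
    counts = [0] * len(positions)
    for j, (c, p) in enumerate(zip(chroms, positions)):
        for ind in samples:
            covered = any(
                s.individual == ind and s.chrom == c and s.start_bp <= p <= s.end_bp
                for s in segments
            )
            counts[j] += covered
    return counts
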