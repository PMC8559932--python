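"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results with the slowest, most literal method
available — exhaustive loops and exact integer arithmetic — and share no
code with the implementation paths they check.
"""

from math import comb

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def brute_force_bp(read: str, intron: str, min_anchor: int = 8, max_mismatch: int = 1):
    """Exhaustive search over every orientation, split and BP position.

    Returns (status, bp_offset, signature, alternatives) mirroring the
    caller's contract: minimal non-BP mismatches win, ties prefer the longer
    exact prefix match of the post-jump anchor, surviving distinct BP
    positions make the read ambiguous with the 3'-most reported first.
    """
    read = read.upper()
    Li = len(intron)
    if len(read) < 2 * min_anchor:
        return ("unalignable", None, None, ())
    cands = []
    for orientation in ("as-is", "reverse-complement"):
        seq = read if orientation == "as-is" else _revcomp(read)
        Lr = len(seq)
        for k in range(min_anchor, Lr - min_anchor + 1):
            L2 = Lr - k
            if L2 > Li or k > Li:
                continue
            post = seq[k:]
            post_mm = sum(x != y for x, y in zip(post, intron[:L2]))
            prefix = 0
            for x, y in zip(post, intron[:L2]):
                if x != y:
                    break
                prefix += 1
            obs = seq[k - 1]
            for p in range(k, Li + 1):  # 1-based BP position
                ref = intron[p - 1]
                if obs == ref:
                    sig = False
                elif ref == "A" and obs == "T":
                    sig = True
                else:
                    continue
                seg = intron[p - k : p - 1]
                pre_mm = sum(x != y for x, y in zip(seq[: k - 1], seg))
                if pre_mm + post_mm <= max_mismatch:
                    cands.append((pre_mm + post_mm, prefix, p, k, orientation, sig))
    if not cands:
        return ("unalignable", None, None, ())
    best_mm = min(c[0] for c in cands)
    cands = [c for c in cands if c[0] == best_mm]
    best_prefix = max(c[1] for c in cands)
    cands = [c for c in cands if c[1] == best_prefix]
    cands.sort(key=lambda c: (-c[2], c[3], c[4]))
    positions = sorted({c[2] for c in cands}, reverse=True)
    mm, prefix, p, k, orientation, sig = cands[0]
    status = "called" if len(positions) == 1 else "ambiguous"
    return (status, p - 1 - Li, sig, tuple(q - 1 - Li for q in positions[1:]))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration in exact
    integer arithmetic (point probabilities compared as integers)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    num_obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = comb(n, c1)
    acc = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(n - r1, c1 - x)
        if num <= num_obs:
            acc += num
    return acc / total
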