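"""Independent brute-force oracle for the 188-D descriptors.

Everything here recomputes descriptors by direct counting and sequential
scans, sharing only the residue-grouping *tables* (data) with the package —
never its counting code — so agreement is a real cross-check.
"""

import math

from mfescan.ctd import GROUPINGS, PROPERTY_ORDER
from mfescan.sequence_io import STANDARD_AA


def brute_aa_composition(seq):
    return [sum(1 for c in seq if c == a) / len(seq) for a in STANDARD_AA]


def brute_group_composition(seq, grouping):
    out = []
    for group in grouping.groups:
        out.append(sum(1 for c in seq if c in group) / len(seq))
    return out


def brute_transition(seq, grouping):
    def gid(c):
        return next(j for j, g in enumerate(grouping.groups) if c in g)

    out = []
    for j, k in ((0, 1), (0, 2), (1, 2)):
        count = 0
        for i in range(len(seq) - 1):
            a, b = gid(seq[i]), gid(seq[i + 1])
            if (a, b) == (j, k) or (a, b) == (k, j):
                count += 1
        out.append(count / (len(seq) - 1))
    return out


def brute_distribution(seq, grouping):
    """Sequential scan: stop at the residue reaching each target count."""
    n = len(seq)
    out = []
    for group in grouping.groups:
        m = sum(1 for c in seq if c in group)
        if m == 0:
            out.extend([0.0] * 5)
            continue
        targets = [1,
                   max(1, math.ceil(0.25 * m)),
                   max(1, math.ceil(0.50 * m)),
                   max(1, math.ceil(0.75 * m)),
                   m]
        for target in targets:
            running = 0
            for pos, c in enumerate(seq, start=1):
                if c in group:
                    running += 1
                    if running == target:
                        out.append(100.0 * pos / n)
                        break
    return out


def brute_encode(seq):
    """Full 188-element vector by direct counting, fixed layout."""
    values = brute_aa_composition(seq)
    for prop in PROPERTY_ORDER:
        grouping = GROUPINGS[prop]
        values += brute_group_composition(seq, grouping)
        values += brute_transition(seq, grouping)
        values += brute_distribution(seq, grouping)
    return values
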