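"""Independent brute-force implementation of the evidence-combining rules.

Written as rule *data* (minimum level counts per rule) rather than
conditionals, so it shares no structure with the engine's combiner.
"""

from collections import Counter

# minimum counts keyed by level: sa=5, vs=4, s=3, m=2, su=1
PATHOGENIC_RULES = (
    {5: 1},
    {4: 1, 3: 1},
    {4: 1, 2: 2},
    {4: 1, 2: 1, 1: 1},
    {4: 1, 1: 2},
    {3: 2},
    {3: 1, 2: 3},
    {3: 1, 2: 2, 1: 2},
    {3: 1, 2: 1, 1: 4},
)

LIKELY_PATHOGENIC_RULES = (
    {4: 1, 2: 1},
    {3: 1, 2: 1},
    {3: 1, 1: 2},
    {2: 3},
    {2: 2, 1: 2},
    {2: 1, 1: 4},
)

BENIGN_RULES = ({5: 1}, {3: 2})

LIKELY_BENIGN_RULES = ({3: 1, 1: 1}, {1: 2})


def _matches(counts: Counter, rules) -> bool:
    return any(
        all(counts[level] >= n for level, n in rule.items()) for rule in rules
    )


def oracle_combine(path_levels, benign_levels, high=4, low=2):
    """(category name, conflict stage) for two level multisets."""
    p = Counter(path_levels)
    b = Counter(benign_levels)
    p_sum = sum(path_levels)
    b_sum = sum(benign_levels)

    if p_sum >= high and b_sum >= high:
        return "Uncertain", "high"
    if _matches(p, PATHOGENIC_RULES):
        return "Pathogenic", "none"
    if _matches(b, BENIGN_RULES):
        return "Benign", "none"
    if p_sum >= low and b_sum >= low:
        return "Uncertain", "low"
    if _matches(p, LIKELY_PATHOGENIC_RULES):
        return "LikelyPathogenic", "none"
    if _matches(b, LIKELY_BENIGN_RULES):
        return "LikelyBenign", "none"
    return "Uncertain", "none"
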