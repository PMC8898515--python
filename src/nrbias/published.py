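"""Published summary numbers from the motivating trial, used as inputs.

The motivating study — a gender-blocked 3x2x2 factorial mailed-survey
experiment among 960 OEF/OIF/OND Veterans applying for PTSD disability
benefits — reports per-arm return counts and per-mechanism prevalence
triplets. Its unit-level data are not public, but these printed summaries
are exact inputs for worked-example checks of the package's arithmetic
(RR1 rates, cross-mechanism variance and range, bias differences).
"""

from __future__ import annotations

#: (returned, assigned) by block and stratum. Strata: overall, the three
#: content levels, the two source levels, the two incentive levels.
RESPONSE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "men": {
        "overall": (199, 480),
        "content=combat": (70, 160),
        "content=sexual_attention": (69, 160),
        "content=lifetime": (60, 160),
        "source=oef_list": (88, 240),
        "source=claims_list": (111, 240),
        "incentive=usd20": (86, 240),
        "incentive=usd40": (113, 240),
    },
    "women": {
        "overall": (211, 480),
        "content=combat": (64, 160),
        "content=sexual_attention": (75, 160),
        "content=lifetime": (72, 160),
        "source=oef_list": (102, 240),
        "source=claims_list": (109, 240),
        "incentive=usd20": (94, 240),
        "incentive=usd40": (117, 240),
    },
}

#: Printed (MCAR, MAR, MNAR) prevalence percents by (block, outcome,
#: stratum) — the inputs of the cross-mechanism summary worked examples.
MECHANISM_TRIPLETS: dict[tuple[str, str, str], tuple[float, float, float]] = {
    ("men", "self_combat", "overall"): (89.3, 85.3, 66.8),
    ("men", "self_combat", "incentive=usd20"): (92.3, 89.9, 72.5),
    ("men", "self_msa", "overall"): (5.2, 5.6, 25.6),
    ("men", "self_msa", "incentive=usd40"): (4.1, 4.4, 18.3),
    ("women", "self_combat", "overall"): (64.2, 62.3, 55.6),
    ("women", "self_msa", "overall"): (50.1, 51.0, 49.8),
}

#: (respondent %, frame %) pairs for bias worked examples.
BIAS_EXAMPLES: dict[tuple[str, str], tuple[float, float]] = {
    ("men", "any_benefits"): (86.9, 81.9),
    ("men", "age_lt30"): (23.6, 30.4),
}
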