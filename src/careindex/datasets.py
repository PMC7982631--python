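"""Published GBD 2017 global thyroid-cancer reference values.

All-age global counts for 1990 and 2017 by sex, and the counterfactual
expected incident counts of the published global trend decomposition.
These printed estimates serve as small worked-example inputs: recomputing
ratio indices, percent changes and decomposition contributions from them
checks the arithmetic of this package against the published analysis.
"""

from __future__ import annotations

#: All-age global counts: {(year, sex): {measure: count}}.
GLOBAL_COUNTS: dict[tuple[int, str], dict[str, float]] = {
    (1990, "both"): {"prevalence": 772_090, "incidence": 95_026,
                     "deaths": 22_065, "dalys": 648_235,
                     "ylls": 599_107, "ylds": 49_129},
    (1990, "female"): {"prevalence": 585_224, "incidence": 70_852,
                       "deaths": 14_509, "dalys": 421_306,
                       "ylls": 385_301, "ylds": 36_005},
    (1990, "male"): {"prevalence": 186_866, "incidence": 24_174,
                     "deaths": 7_557, "dalys": 226_929,
                     "ylls": 213_806, "ylds": 13_124},
    (2017, "both"): {"prevalence": 2_144_939, "incidence": 255_489,
                     "deaths": 41_235, "dalys": 1_133_175,
                     "ylls": 1_001_180, "ylds": 131_995},
    (2017, "female"): {"prevalence": 1_530_875, "incidence": 179_401,
                       "deaths": 24_076, "dalys": 664_929,
                       "ylls": 573_957, "ylds": 90_972},
    (2017, "male"): {"prevalence": 614_063, "incidence": 76_088,
                     "deaths": 17_159, "dalys": 468_246,
                     "ylls": 427_223, "ylds": 41_024},
}

#: Global decomposition inputs: incident counts observed in 1990 and 2017
#: and the published expected counts under the growth-only and
#: growth-plus-aging counterfactual scenarios.
GLOBAL_DECOMPOSITION_COUNTS: dict[str, dict[str, float]] = {
    "both": {"n_ref": 95_026, "n_cur": 255_489,
             "e_growth": 143_690, "e_growth_aging": 171_003},
    "female": {"n_ref": 70_852, "n_cur": 179_401,
               "e_growth": 107_541, "e_growth_aging": 126_227},
    "male": {"n_ref": 24_174, "n_cur": 76_088,
             "e_growth": 36_416, "e_growth_aging": 44_676},
}
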