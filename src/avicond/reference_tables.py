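"""Published summary figures from an 11-year (January 2009 – November
2019) condemnation series of a Brazilian export poultry slaughterhouse.

The raw monthly spreadsheets behind that series are not publicly
deposited; what survives in print are period totals, the per-cause
frequency table, species-mix group summaries and a handful of index
values. Those printed numbers are shipped here as worked-example inputs
so the package's accounting functions can be exercised against real
published arithmetic.
"""

from __future__ import annotations

#: Birds slaughtered and condemnation records over the full period.
TOTAL_SLAUGHTERED = 785_068_807
TOTAL_CONDEMNED = 55_594_318

#: Published per-cause condemnation counts (partial + total). The printed
#: grand total above is NOT the sum of these rows (55,594,318 vs
#: 53,044,503); percent shares are internally consistent only with the
#: column sum, which is why the frequency table defaults to the
#: sum-of-causes denominator.
CAUSE_COUNTS: dict[str, int] = {
    "contamination": 19_714_313,
    "contusion": 13_969_714,
    "dermatosis": 6_305_341,
    "aerosacculitis": 5_055_339,
    "arthritis": 2_120_165,
    "septicemia": 1_712_767,
    "disgusting_aspects": 1_665_298,
    "excessive_scalding": 1_133_914,
    "cellulitis": 889_035,
    "others": 478_617,
}

#: Turkey slaughter: annual mean over 2009-2016, and the 2017 total after
#: the phase-out began.
TURKEY_ANNUAL_MEAN_2009_2016 = 5_023_045
TURKEY_TOTAL_2017 = 1_789_429
TURKEY_TOTAL_2018 = 258_773

#: Published group summaries of per-month percent condemnation ratios
#: (group A: turkey + chicken months, n=110; group B: heavy-chicken-only
#: months, n=21). Values: (mean_a, mean_b) in percent of head slaughtered.
GROUP_MEANS: dict[str, tuple[float, float]] = {
    "total": (6.925, 10.892),
    "contamination": (2.322, 4.484),
    "aerosacculitis": (0.787, 0.001),
    "contusion": (1.658, 3.250),
    "dermatosis": (0.798, 1.065),
}

#: Months removed from the index analyses due to recording inconsistencies.
EXCLUDED_MONTHS = ("2017-06", "2019-12")
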