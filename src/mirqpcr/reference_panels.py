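"""Published candidate lists of the plasma-miRNA RA discovery study this
pipeline models.

These lists are inputs to the bookkeeping operations (panel merging,
delisting): the three phase-1 screening classes, the six manually added
candidates, the eleven confirmation-phase hits, and the quality-based
exclusions, as printed in the source study's results.
"""

#: >= four-fold differential expression on the 3 vs 3 array (10 miRNAs)
PHASE1_FOLD4 = (
    "let-7e",
    "miR-128",
    "miR-323-3p",
    "miR-133b",
    "miR-18b",
    "miR-144",
    "miR-451",
    "miR-150",
    "miR-486-3p",
    "miR-196b-5p",
)

#: detected only in RA plasma, never in controls (3 miRNAs)
PHASE1_RA_ONLY = ("miR-130b-5p", "miR-452", "miR-579")

#: significantly different (p < 0.05) on the array (7 miRNAs)
PHASE1_P05 = (
    "miR-518d-5p",
    "miR-202",
    "miR-193b",
    "miR-26a",
    "miR-30e-3p",
    "miR-885-5p",
    "miR-374b",
)

#: added after manual inspection of the array (borderline p, high-abundance
#: two-fold change, or outlier-driven difference)
MANUAL_ADDITIONS = (
    "miR-24",
    "miR-28-5p",
    "miR-28-3p",
    "miR-30c",
    "miR-125a-5p",
    "miR-126-3p",
)

#: significantly different in the 8 vs 8 confirmation cohort (11 miRNAs)
PHASE2_CONFIRMED = (
    "miR-24",
    "miR-26a",
    "miR-28-5p",
    "miR-28-3p",
    "miR-30c",
    "miR-30e-3p",
    "miR-125a-5p",
    "miR-126-3p",
    "miR-130b-5p",
    "miR-133b",
    "miR-202",
)

#: removed before validation for high Ct and/or degenerate melt curves
DELISTED_QC = {
    "miR-130b-5p": "high_ct",
    "miR-133b": "poor_curve",
    "miR-202": "high_ct",
}

#: normalizer candidate removed for unspecific primers
DELISTED_PRIMER = {"miR-484-5p": "unspecific_primer"}

#: the three-marker logistic panel behind the ePRAM score
EPRAM_PANEL = ("miR-24", "miR-30a-5p", "miR-125a-5p")
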