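"""Bundled worked-example tables from the cross-species comparison.

These are the small printed summary tables of the four-screen
motor-neuron vulnerability comparison (the Brockington, Kaplan, Murray
and Hedlund screens): the top-20 up- and down-regulated genes of the
mouse RNA-seq screen, the six-gene fully concordant fold-change matrix,
the screen roster, and the fly modifier-screen tallies.  They serve as
ready-made inputs for worked examples and consistency checks; the full
deposited per-gene lists are not redistributed here.
"""

from __future__ import annotations

import pandas as pd

from concord.io import ScreenResult

SCREEN_IDS = ("brockington", "kaplan", "murray", "hedlund")

#: screen roster: species and the disease context defining vulnerability
SCREEN_ROSTER = pd.DataFrame(
    [
        ("brockington", "human", "ALS", "cervical MNs", "oculomotor nucleus"),
        ("kaplan", "mouse", "ALS", "lumbar spinal cord (L5)", "oculomotor nucleus"),
        ("murray", "mouse", "SMA", "abdominal MNs", "cranial MNs"),
        ("hedlund", "rat", "SBMA/ALS/SMA", "cervical MNs", "oculomotor/abducens"),
    ],
    columns=["screen_id", "species", "vulnerable_in", "vulnerable", "resistant"],
)

#: top-20 up- and down-regulated genes of the mouse RNA-seq screen
#: (gene, log2 fold change vulnerable vs resistant, adjusted p)
TOP20_UP = [
    ("Hoxc8", 11.1, 9e-06), ("Hoxd8", 10.4, 1e-03), ("Hoxc9", 7.8, 6e-04),
    ("Hoxa5", 7.1, 1e-07), ("D930020B18Rik", 6.8, 1e-02), ("Npy5r", 6.8, 2e-03),
    ("BC023105", 6.5, 5e-03), ("AU021034", 6.3, 5e-04), ("AV039307", 6.2, 2e-05),
    ("Mstn", 5.6, 1e-04), ("Hoxb7", 5.5, 3e-05), ("Gm20520", 5.4, 2e-02),
    ("BC037032", 5.4, 1e-03), ("Hoxd9", 5.4, 5e-03), ("Troap", 5.3, 2e-02),
    ("Prss56", 5.3, 4e-02), ("Thpo", 5.2, 2e-04), ("Mpz", 5.2, 2e-04),
    ("Gm5077", 5.0, 3e-03), ("Glp1r", 5.0, 4e-04),
]

TOP20_DOWN = [
    ("Ptgds", -11.0, 0.0), ("Tbx15", -10.0, 9e-05), ("Glis1", -9.7, 3e-04),
    ("Slc6a4", -9.6, 1e-03), ("Tph2", -9.4, 1e-06), ("Omd", -9.2, 5e-02),
    ("Fam180a", -8.9, 9e-06), ("Gm15605", -8.8, 1e-02), ("Cdh1", -8.7, 2e-09),
    ("Insm1", -8.6, 9e-05), ("Nov", -8.5, 1e-13), ("Moxd1", -8.5, 3e-05),
    ("Slc17a7", -8.2, 8e-05), ("Ogn", -8.1, 0.0), ("Gal", -7.9, 1e-04),
    ("Gxylt2", -7.6, 5e-03), ("Thbd", -7.5, 2e-13), ("Trim58", -7.4, 9e-11),
    ("Cyp2f2", -7.3, 4e-02), ("Aldh1a2", -7.2, 7e-11),
]

#: log2 fold changes of the six genes concordant in all four screens
CROSS_SCREEN_LOG2FC = pd.DataFrame(
    {
        "brockington": [-3.3, -3.1, -1.5, -1.3, -1.4, 2.9],
        "kaplan": [-1.4, -3.8, -0.8, -1.1, -0.8, 3.5],
        "murray": [-2.0, -3.9, -1.6, -1.8, -1.6, 7.1],
        "hedlund": [-2.7, -2.1, -2.6, -2.0, -1.0, 3.7],
    },
    index=["Celf5", "Col5a2", "Pgrmc1", "Snca", "Stmn1", "Hoxa5"],
)

#: fly modifier-screen tallies: candidate funnel and outcome
FLY_SCREEN = {
    "n_candidates": 160,        # tier >= 3 plus top axonal/synaptic clusters
    "n_with_fly_homolog": 116,
    "n_up_regulated": 39,
    "n_down_regulated": 77,
    "n_lines_tested": 66,
    "n_suppressors": 7,
    "n_enhancers": 4,
}

#: reported filter tallies of the mouse RNA-seq screen (q < 0.05,
#: fold change > 1.5): kept / up / down
RNASEQ_FILTER_TALLIES = {"kept": 910, "up": 218, "down": 692}

#: reported concordance-list sizes (exclusive tiers)
TIER_LIST_SIZES = {2: 595, 3: 62, 4: 6}


def top20_screen() -> ScreenResult:
    """The top-20 table as a ScreenResult (p unreported, copied from q)."""
    rows = [(g, fc, q, q) for g, fc, q in TOP20_UP + TOP20_DOWN]
    records = pd.DataFrame(rows, columns=["gene", "log2fc", "p", "q"])
    return ScreenResult("murray", "mouse", records)


def cross_screen_results() -> list[ScreenResult]:
    """The fully concordant six-gene matrix as one ScreenResult per screen.

    Fold changes are log2; all entries passed each screen's significance
    filter, so q is coded as 0 (significant by construction).
    """
    screens = []
    roster = SCREEN_ROSTER.set_index("screen_id")
    for sid in CROSS_SCREEN_LOG2FC.columns:
        records = pd.DataFrame(
            {
                "gene": CROSS_SCREEN_LOG2FC.index,
                "log2fc": CROSS_SCREEN_LOG2FC[sid].to_numpy(),
                "p": 0.0,
                "q": 0.0,
            }
        )
        screens.append(ScreenResult(sid, roster.loc[sid, "species"], records))
    return screens
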