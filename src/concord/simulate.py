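"""Synthetic multi-screen and phenotype data with known ground truth.

The multi-screen generator emulates the structure the concordance
analysis assumes: several screens over up to three species measuring a
shared gene set, with a planted subset of genes whose group-mean shift
has a common sign in every screen (concordant), a subset whose sign
flips in one screen (discordant), screen-specific gaussian noise on the
log2 scale and per-screen coverage dropout.  Species namespaces differ
in case convention and are linked by a generated homology map, so the
full harmonisation path is exercised.  All generators are deterministic
under a master seed, from which per-screen substreams are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from concord.io import ExpressionMatrix, PhenotypeTables
from concord.homology import HomologyMap, canonical_symbol

#: species assignment mirroring the four source screens
DEFAULT_SPECIES_CYCLE = ("mouse", "human", "mouse", "rat")

#: preset reproducing the baseline parameter-recovery study conditions
RECOVERY_PRESET = dict(
    n_genes=2000,
    n_concordant=50,
    n_discordant=20,
    effect_log2=1.0,
    noise_sd=0.25,
    replicates=4,
    n_screens=4,
    coverage=1.0,
)


@dataclass
class SimScreen:
    """One simulated screen: an expression matrix in its own namespace."""

    screen_id: str
    species: str
    matrix: ExpressionMatrix


@dataclass
class SimTruth:
    """Ground truth for a simulated multi-screen experiment.

    Effects are keyed by reference (mouse) symbol; a gene absent from a
    screen's effect map was not measured there (coverage dropout).
    """

    planted_concordant: dict[str, dict[str, float]]
    planted_discordant: dict[str, dict[str, float]]
    null_genes: set[str] = field(default_factory=set)
    noise_sd: dict[str, float] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc, disc = set(self.planted_concordant), set(self.planted_discordant)
        if conc & disc or conc & self.null_genes or disc & self.null_genes:
            raise ValueError("planted/null gene sets must be disjoint")


@dataclass
class RecoveryReport:
    """Sensitivity/precision of planted-gene recovery, per tier.

    ``per_tier`` rows are cumulative (tier >= k): sensitivity is the
    fraction of planted concordant genes recovered, precision the
    fraction of called genes that were planted (NaN when nothing is
    called, flagged via ``precision_defined``).
    """

    per_tier: pd.DataFrame
    n_discordant_called: int

    def sensitivity(self, k: int) -> float:
        return float(self.per_tier.loc[k, "sensitivity"])

    def precision(self, k: int) -> float:
        return float(self.per_tier.loc[k, "precision"])


def _species_symbol(ref: str, species: str) -> str:
    return ref.upper() if species == "human" else canonical_symbol(ref, species)


def gen_multiscreen(
    n_genes: int = 2000,
    n_concordant: int = 50,
    n_discordant: int = 20,
    effect_log2: float = 1.0,
    noise_sd: float = 0.25,
    replicates: int = 4,
    n_screens: int = 4,
    coverage: float | Sequence[float] = 1.0,
    seed: int | None = None,
    species_cycle: Sequence[str] = DEFAULT_SPECIES_CYCLE,
) -> tuple[list[SimScreen], HomologyMap, SimTruth]:
    """Simulate replicate-level expression matrices for several screens.

    Planted concordant genes shift the vulnerable-group mean by a signed
    ``effect_log2`` with the same sign in every screen; discordant genes
    flip sign in one randomly chosen screen; null genes shift by 0.
    Gaussian noise with sd ``noise_sd`` (log2 units) is added per
    replicate, and each screen measures a random ``coverage`` fraction
    of the gene universe.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_concordant + n_discordant > n_genes:
        raise ValueError("planted genes exceed the gene universe")
    if replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    cov = np.broadcast_to(np.asarray(coverage, float), (n_screens,)).copy()
    if ((cov <= 0) | (cov > 1)).any():
        raise ValueError(f"coverage fractions must be in (0, 1], got {cov}")

    if effect_log2 == 0:
        # a zero effect plants nothing: every gene is null
        n_concordant = n_discordant = 0

    master = np.random.default_rng(seed)
    ref_symbols = [f"Simg{i:04d}" for i in range(1, n_genes + 1)]
    screen_ids = [f"screen{i + 1}" for i in range(n_screens)]
    species = [species_cycle[i % len(species_cycle)] for i in range(n_screens)]

    chosen = master.choice(n_genes, size=n_concordant + n_discordant, replace=False)
    concordant = [ref_symbols[i] for i in chosen[:n_concordant]]
    discordant = [ref_symbols[i] for i in chosen[n_concordant:]]
    base_sign = {
        g: (1.0 if master.random() < 0.5 else -1.0) for g in concordant + discordant
    }
    flip_screen = {g: int(master.integers(n_screens)) for g in discordant}
    baseline = master.normal(8.0, 2.0, size=n_genes)

    truth = SimTruth(
        planted_concordant={g: {} for g in concordant},
        planted_discordant={g: {} for g in discordant},
        null_genes=set(ref_symbols) - set(concordant) - set(discordant),
        noise_sd={sid: noise_sd for sid in screen_ids},
        coverage=dict(zip(screen_ids, cov.tolist())),
    )

    screens: list[SimScreen] = []
    sub_seeds = master.integers(0, 2**31 - 1, size=n_screens)
    for s, (sid, spc) in enumerate(zip(screen_ids, species)):
        rng = np.random.default_rng(sub_seeds[s])
        n_measured = max(2, int(round(cov[s] * n_genes)))
        measured_idx = np.sort(rng.choice(n_genes, size=n_measured, replace=False))
        measured = [ref_symbols[i] for i in measured_idx]

        effects = np.zeros(n_measured)
        for row, ref in enumerate(measured):
            if ref in base_sign:
                sign = base_sign[ref]
                if ref in flip_screen and flip_screen[ref] == s:
                    sign = -sign
                effects[row] = sign * effect_log2
                store = (
                    truth.planted_concordant
                    if ref in truth.planted_concordant
                    else truth.planted_discordant
                )
                store[ref][sid] = effects[row]

        means = baseline[measured_idx]
        vuln = (
            means[:, None]
            + effects[:, None]
            + rng.normal(0, noise_sd, size=(n_measured, replicates))
        )
        resi = means[:, None] + rng.normal(0, noise_sd, size=(n_measured, replicates))
        samples = [f"{sid}_V{r + 1}" for r in range(replicates)] + [
            f"{sid}_R{r + 1}" for r in range(replicates)
        ]
        values = pd.DataFrame(
            np.hstack([vuln, resi]),
            index=[_species_symbol(g, spc) for g in measured],
            columns=samples,
        )
        groups = pd.Series(
            ["vulnerable"] * replicates + ["resistant"] * replicates,
            index=samples,
            name="group",
        )
        screens.append(SimScreen(sid, spc, ExpressionMatrix(values, groups)))

    rows = []
    for i, ref in enumerate(ref_symbols):
        gid = f"hg{i + 1:05d}"
        for spc in sorted(set(species) | {"mouse"}):
            rows.append((gid, spc, _species_symbol(ref, spc)))
    homology = HomologyMap(
        groups=pd.DataFrame(rows, columns=["group_id", "species", "symbol"])
    )
    return screens, homology, truth


def gen_phenotypes(
    n_lines: int = 10,
    planted_modifiers: Mapping[str, float] | None = None,
    n_flies: int = 12,
    n_mice: int = 12,
    hazard_ratio: float = 1.0,
    control_area: float = 0.10,
    area_sd: float = 0.012,
    baseline_median_day: float = 26.0,
    censor_day: float = 150.0,
    endplate_groups: Mapping[str, float] | None = None,
    n_muscles: int = 8,
    endplates_per_muscle: int = 120,
    seed: int | None = None,
) -> tuple[PhenotypeTables, dict]:
    """Simulate the three validation phenotype tables with truth labels.

    Eye areas are gaussian around the disease-model control mean (mm^2,
    per fly, averaged over two eyes) plus each line's planted effect;
    survival is exponential with the given hazard ratio for the second
    group and administrative censoring at ``censor_day``; endplate
    counts are trinomial with a group-specific fully-occupied
    probability (remaining mass split 2:1 between partial and vacant).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_lines < 1 or n_flies < 2 or n_mice < 2 or n_muscles < 1:
        raise ValueError("counts must be positive (>= 2 per group for tests)")
    rng = np.random.default_rng(seed)
    planted = dict(planted_modifiers or {})
    endplate_groups = dict(
        endplate_groups or {"untreated": 0.60, "treated": 0.95}
    )

    # fly eye areas: control line plus n_lines candidate lines
    area_rows = []
    line_ids = ["control"] + [f"line{i + 1:02d}" for i in range(n_lines)]
    effects = {line: float(planted.get(line, 0.0)) for line in line_ids[1:]}
    for line in line_ids:
        shift = effects.get(line, 0.0)
        for fly in range(n_flies):
            area_rows.append(
                {
                    "line_id": line,
                    "genotype_class": "disease_control" if line == "control" else "candidate",
                    "fly_id": f"{line}_f{fly + 1}",
                    "area": max(1e-4, rng.normal(control_area + shift, area_sd)),
                }
            )

    # mouse survival: exponential; group b hazard scaled by hazard_ratio
    lam = np.log(2) / baseline_median_day
    surv_rows = []
    for group, h in (("untreated", lam), ("treated", lam * hazard_ratio)):
        times = rng.exponential(1 / h, size=n_mice)
        for m, t in enumerate(times):
            censored = t > censor_day
            surv_rows.append(
                {
                    "animal_id": f"{group}_m{m + 1}",
                    "group": group,
                    "day": round(min(t, censor_day), 1) + 0.1,
                    "event": "censored" if censored else "death",
                }
            )

    # endplate occupancy: trinomial per muscle
    end_rows = []
    for group, p_full in endplate_groups.items():
        p_partial = (1 - p_full) * 2 / 3
        p_vacant = (1 - p_full) / 3
        for m in range(n_muscles):
            counts = rng.multinomial(endplates_per_muscle, [p_full, p_partial, p_vacant])
            end_rows.append(
                {
                    "muscle_id": f"{group}_u{m + 1}",
                    "group": group,
                    "n_full": int(counts[0]),
                    "n_partial": int(counts[1]),
                    "n_vacant": int(counts[2]),
                }
            )

    tables = PhenotypeTables(
        eye_areas=pd.DataFrame(area_rows),
        survival=pd.DataFrame(surv_rows),
        endplates=pd.DataFrame(end_rows),
    )
    truth = {
        "modifier_effects": effects,
        "hazard_ratio": hazard_ratio,
        "endplate_p_full": endplate_groups,
        "control_area": control_area,
    }
    return tables, truth


def evaluate_recovery(matrix, truth: SimTruth) -> RecoveryReport:
    """Score a concordance matrix against the planted truth.

    Per cumulative tier k: sensitivity = planted concordant genes called
    at tier >= k divided by all planted; precision = planted among the
    called.  Also counts planted discordant genes wrongly called
    concordant in 2 or more screens.
    """
    planted = set(truth.planted_concordant)
    universe = planted | set(truth.planted_discordant) | truth.null_genes
    called_symbols = set(matrix.ref_symbols)
    if called_symbols and not (called_symbols & universe):
        raise ValueError("matrix and truth share no symbols; namespace mismatch?")

    n_screens = len(matrix.screens)
    rows = []
    for k in range(1, n_screens + 1):
        called = {
            s for s in matrix.ref_symbols
            if matrix.tier[s] >= k and matrix.direction[s] in ("up", "down")
        }
        tp = len(called & planted)
        rows.append(
            {
                "k": k,
                "n_called": len(called),
                "sensitivity": tp / len(planted) if planted else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
                "precision_defined": bool(called),
            }
        )
    discordant_called = {
        s for s in matrix.ref_symbols
        if s in truth.planted_discordant
        and matrix.tier[s] >= 2
        and matrix.direction[s] in ("up", "down")
    }
    return RecoveryReport(
        per_tier=pd.DataFrame(rows).set_index("k"),
        n_discordant_called=len(discordant_called),
    )
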