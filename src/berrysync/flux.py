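"""Per-fruit solute flux accounting, phloem-arrest detection and tonoplast
sugar-transport energetics.

The central accounting identity is amount = concentration x volume: solute
contents per fruit (not concentrations) are what phloem import delivers,
so the simultaneous stop of water, sugar and K+ import shows up as stage
amounts that no longer differ between the growth peak (P) and the
shrivelling stage (S) while both differ from the growing stage (G).  Stage
comparisons use one-way ANOVA with Tukey's HSD (Tukey-Kramer for unequal
n) summarised as a compact letter display.

The energetics half quantifies two Discussion-level calculations: the
fraction of tonoplast-exported H+ scavenged by cytosolic malate
metabolism (both malate oxidation and gluconeogenesis consume 2 H+ per
malate), and the equilibrium cytosolic sugar concentration imposed by an
nH+/sucrose antiport across a steep vacuolar pH gradient.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnergeticsScenario",
    "TukeyReport",
    "ArrestReport",
    "solute_amount",
    "normalize_amount",
    "stage_tukey",
    "detect_arrest",
    "proton_budget",
    "antiport_equilibrium",
    "malate_meq_to_mmol",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)


@dataclass(frozen=True)
class EnergeticsScenario:
    """Stoichiometric and thermodynamic knobs for the tonoplast budget.

    ``h_per_sucrose`` is the antiport stoichiometry n (H+ exported to the
    cytosol per sucrose moved into the vacuole; default 1).  Both malate
    oxidation (2 H+ + malate + 3 O2 -> 4 CO2 + 3 H2O) and malate
    gluconeogenesis (2 malate + 4 H+ -> hexose + 2 CO2) consume 2 H+ per
    malate.  ``membrane_potential_mv`` is psi(cytosol) - psi(vacuole).
    """

    h_per_sucrose: float = 1.0
    h_consumed_per_malate: float = 2.0
    pH_vac: float = 2.7
    pH_cyt: float = 7.5
    membrane_potential_mv: float = 0.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.h_per_sucrose <= 0 or self.h_consumed_per_malate <= 0:
            raise ValueError("stoichiometries must be positive")
        for ph in (self.pH_vac, self.pH_cyt):
            if not 0.0 <= ph <= 14.0:
                raise ValueError("pH must lie in [0, 14]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


def solute_amount(concentration, volume_ml):
    """Per-fruit amount Q = c x V.

    mol/L x mL -> mmol; mEq/L inputs pass through as mEq amounts
    (mEq/L x mL / 1000).  Scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    v = np.asarray(volume_ml, dtype=float)
    if np.any(c < 0) or np.any(v < 0):
        raise ValueError("concentration and volume must be non-negative")
    out = c * v
    return float(out) if np.ndim(out) == 0 else out


def meq_amount(concentration_meq_l, volume_ml):
    """Amount in mEq from a mEq/L concentration and a mL volume."""
    return solute_amount(concentration_meq_l, volume_ml) / 1000.0


def malate_meq_to_mmol(meq):
    """Malate is divalent: 2 mEq = 1 mmol."""
    return np.asarray(meq, dtype=float) / 2.0


def normalize_amount(amounts, pericarp_mass_at_arrest_g):
    """Scale per-berry amounts to a reference 1 g of pericarp at arrest.

    Accepts scalars/arrays for both; each berry's amounts are multiplied
    by 1 g / (its pericarp mass at phloem arrest), making contents
    comparable across berries and genotypes.
    """
    mass = np.asarray(pericarp_mass_at_arrest_g, dtype=float)
    if np.any(~np.isfinite(mass)) or np.any(mass <= 0):
        raise ValueError("pericarp mass at arrest must be positive and finite")
    out = np.asarray(amounts, dtype=float) / mass
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display


@dataclass
class TukeyReport:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject
    letters: dict  # group -> letter string
    group_means: dict
    excluded: list


def _compact_letter_display(groups, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.
    """
    letters: list[set] = [set(groups)]
    for a, b in significant_pairs:
        new_letters = []
        for col in letters:
            if a in col and b in col:
                new_letters.append(col - {a})
                new_letters.append(col - {b})
            else:
                new_letters.append(col)
        # absorb columns contained in others
        letters = []
        for col in new_letters:
            if not any(col < other for other in new_letters if other is not col):
                if col and col not in letters:
                    letters.append(col)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, col in enumerate(sorted(letters, key=lambda c: sorted(c))):
        for g in col:
            out[g] += alphabet[i]
    return {g: "".join(sorted(s)) for g, s in out.items()}


def stage_tukey(values, groups, alpha: float = 0.05) -> TukeyReport:
    """One-way ANOVA + Tukey HSD (studentized range, Tukey-Kramer for
    unequal n) with a compact letter display.

    Groups with fewer than 2 observations are excluded with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    sizes = df.groupby("group").size()
    excluded = sorted(sizes[sizes < 2].index.tolist())
    if excluded:
        warnings.warn(f"stage_tukey: excluding groups with <2 replicates: {excluded}")
        df = df[~df["group"].isin(excluded)]
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need >=2 groups with >=2 replicates")
    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in names]
    f_stat, f_p = stats.f_oneway(*arrays)

    hsd = stats.tukey_hsd(*arrays)  # studentized range, Tukey-Kramer for unequal n
    rows = []
    sig_pairs = []
    for (i, a_name), (j, b_name) in itertools.combinations(enumerate(names), 2):
        diff = arrays[j].mean() - arrays[i].mean()
        p_adj = float(hsd.pvalue[i, j])
        reject = p_adj < alpha
        rows.append({"group_a": a_name, "group_b": b_name, "mean_diff": diff,
                     "p_adj": p_adj, "reject": reject})
        if reject:
            sig_pairs.append((a_name, b_name))
    letters = _compact_letter_display(names, sig_pairs)
    return TukeyReport(
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise=pd.DataFrame(rows),
        letters=letters,
        group_means={g: float(a.mean()) for g, a in zip(names, arrays)},
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# arrest detection


@dataclass
class ArrestReport:
    per_solute: pd.DataFrame  # solute, arrested, letters, conclusive
    simultaneous: bool
    conclusive: bool


def _solute_arrested(report: TukeyReport, rule: str) -> bool:
    """Arrest decision from the stage comparison.

    ``shared_letter``: P and S share a Tukey letter while G shares none
    with either (amounts constant from P onward).  ``one_sided``
    (default): G separates from both P and S and lies below P, and S does
    not significantly *exceed* P — a significant P->S decrease (ongoing
    evaporation for water, respiration for sugar) does not contradict the
    arrest of import.
    """
    letters = report.letters
    if not {"G", "P", "S"} <= set(letters):
        return False
    g_separate = not (set(letters["G"]) & (set(letters["P"]) | set(letters["S"])))
    if rule == "shared_letter":
        return g_separate and bool(set(letters["P"]) & set(letters["S"]))
    if rule != "one_sided":
        raise ValueError(f"unknown arrest rule {rule!r}")
    pw = report.pairwise.set_index(["group_a", "group_b"])
    ps = pw.loc[("P", "S")] if ("P", "S") in pw.index else pw.loc[("S", "P")]
    s_exceeds = bool(ps["reject"]) and report.group_means["S"] > report.group_means["P"]
    g_below = report.group_means["G"] < report.group_means["P"]
    return g_separate and g_below and not s_exceeds


def detect_arrest(stage_amounts: dict, alpha: float = 0.05,
                  rule: str = "one_sided") -> ArrestReport:
    """Declare phloem arrest per solute and the simultaneity flag.

    ``stage_amounts`` maps solute name -> (amounts, stage_labels) or
    (amounts, stage_labels, block_labels).  Blocks (e.g. genotype in a
    pooled multi-genotype cohort) are removed as additive effects before
    the stage comparison — solute *levels* differ between genotypes even
    after 1-g normalisation, but the arrest pattern is shared.  A solute
    with any stage below 2 replicates is inconclusive; the simultaneous
    flag requires water, sugar and K+ all arrested at P.  See
    :func:`_solute_arrested` for the two decision rules.
    """
    rows = []
    arrested_map = {}
    conclusive_all = True
    for solute, spec in stage_amounts.items():
        amounts, labels = spec[0], np.asarray(spec[1])
        if len(spec) > 2 and spec[2] is not None:
            blocks = np.asarray(spec[2])
            amounts = np.asarray(amounts, dtype=float)
            grand = amounts.mean()
            centred = amounts.copy()
            for b in np.unique(blocks):
                centred[blocks == b] += grand - amounts[blocks == b].mean()
            amounts = centred
        sizes = pd.Series(labels).value_counts()
        conclusive = all(sizes.get(s, 0) >= 2 for s in ("G", "P", "S"))
        if conclusive:
            report = stage_tukey(amounts, labels, alpha=alpha)
            arrested = _solute_arrested(report, rule)
            letters = report.letters
        else:
            arrested = False
            letters = {}
        conclusive_all &= conclusive
        arrested_map[solute] = arrested
        rows.append({"solute": solute, "arrested": arrested, "conclusive": conclusive,
                     "letters": ";".join(f"{g}={l}" for g, l in sorted(letters.items()))})
    core = [s for s in ("water", "sugar", "potassium") if s in arrested_map]
    simultaneous = bool(core) and all(arrested_map[s] for s in core) and conclusive_all
    return ArrestReport(pd.DataFrame(rows), simultaneous, conclusive_all)


# ---------------------------------------------------------------------------
# energetics


def proton_budget(delta_hexose_mol, delta_malate_mol,
                  scenario: EnergeticsScenario | None = None) -> float:
    """Fraction of tonoplast-exported H+ scavenged by malate metabolism.

    Sucrose delivers 2 hexoses, so the sucrose flux is delta_hexose / 2
    and the H+ export is (delta_hexose / 2) x n.  Malate consumption
    scavenges ``h_consumed_per_malate`` H+ per malate (capped at the
    export).  Returns a fraction in [0, 1].
    """
    scenario = scenario or EnergeticsScenario()
    if delta_hexose_mol <= 0:
        raise ValueError("proton budget undefined for non-positive hexose flux")
    if delta_malate_mol < 0:
        raise ValueError("malate flux must be non-negative")
    h_exported = (delta_hexose_mol / 2.0) * scenario.h_per_sucrose
    h_scavenged = min(scenario.h_consumed_per_malate * delta_malate_mol, h_exported)
    return h_scavenged / h_exported


def antiport_equilibrium(vac_conc_mol_l: float,
                         scenario: EnergeticsScenario | None = None) -> float:
    """Equilibrium cytosolic sugar concentration for an nH+/sucrose antiport.

    [S]_cyt = [S]_vac x 10^(-n (pH_cyt - pH_vac)) x exp(-n F dPsi / RT)

    with n = ``h_per_sucrose`` and dPsi = psi_cyt - psi_vac (V).  At
    dpH = 0 and dPsi = 0 this reduces to [S]_cyt = [S]_vac; a vacuole at
    pH 2.7 against a cytosol at pH 7.5 drives [S]_cyt down by 10^-4.8 per
    exchanged proton.
    """
    scenario = scenario or EnergeticsScenario()
    if vac_conc_mol_l < 0:
        raise ValueError("vacuolar concentration must be non-negative")
    n = scenario.h_per_sucrose
    dph = scenario.pH_cyt - scenario.pH_vac
    dpsi = scenario.membrane_potential_mv / 1000.0
    electro = math.exp(-n * FARADAY * dpsi / (GAS_CONSTANT * scenario.temperature))
    return vac_conc_mol_l * 10.0 ** (-n * dph) * electro
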