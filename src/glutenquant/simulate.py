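"""Synthetic proteome and MRM peak-area generator with known ground truth.

The generator emulates the study design this package targets: two flour
samples (GW, a reduced-gluten wheat; MW, a mixed-wheat control) times
four technical replicates, monitored tryptic and chymotryptic peptides
from the seven prolamin/allergen families, per-peptide log-normal
response factors, and replicate-level log-normal technical noise.

Planting works at the level the pipeline actually estimates. Every
peptide is normalized to its mean over all replicates, so for a peptide
with true GW:MW ratio r the normalized sample means are 2r/(1+r) and
2/(1+r), and any summed group or epitope-category ratio equals
(n - W) / W with W = sum over member peptides of 1/(1+r_i). The packaged
paper scenario therefore solves per-protein true ratios in closed form
from the realized monitored-peptide counts so that the planted
aggregates hold exactly before noise: net canonical gluten 67%,
coeliac HLA-DQ epitope peptides 67%, baker's asthma 180%, wheat allergy
379%, WDEIA 17.7%, and a combined allergy total of 153.5% (the latter
forces exactly one peptide shared between the BA and WA categories,
because with disjoint categories the combined ratio would already be
fixed by the counts alone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .digestion import (
    CANONICAL_GLUTEN_GROUPS,
    DigestionRules,
    ProteinRecord,
    _occurrences,
    digest,
    filter_candidates,
)
from .epitopes import Epitope

# ---------------------------------------------------------------------------
# scenario configuration

#: Residue alphabet for filler peptides, biased toward the Q/P-rich
#: composition of prolamin repeat regions. K/R excluded (cleavage sites
#: are placed explicitly); X excluded (candidates must be matchable).
_FILLER_ALPHABET = list("QQQQPPPLSVAGFITEND")


@dataclass(frozen=True)
class SpecialPeptide:
    """A designed epitope-bearing tryptic peptide hosted by its own
    dedicated carrier protein.

    ``sequence`` may be left None, in which case the generator
    synthesizes one: the epitope core(s) framed by random tryptic-clean
    Q/P-rich flanks, rejection-sampled so the peptide maps uniquely and
    contains no epitope of any other targeted category.
    """

    name: str
    group: str
    epitopes: tuple[tuple[str, str], ...]  # (epitope sequence, category)
    sequence: str | None = None
    ratio: float | None = None  # None -> solved from the scenario targets


@dataclass
class ScenarioTargets:
    """Planted aggregate truths, as GW/MW fractions."""

    net_gluten: float = 0.67
    group_ratios: dict = field(default_factory=dict)  # e.g. omega pinned at 1.0
    category_ratios: dict = field(default_factory=dict)
    allergy_total: float | None = None


@dataclass
class ScenarioConfig:
    seed: int = 0
    n_replicates: int = 4
    background_proteins: dict = field(
        default_factory=lambda: {g: 1 for g in CANONICAL_GLUTEN_GROUPS + ("alp", "ati")}
    )
    peptides_per_background_protein: int = 2  # monitored tryptic units
    include_chymotryptic: bool = True
    baseline_ratios: dict = field(
        default_factory=lambda: {g: 1.0 for g in CANONICAL_GLUTEN_GROUPS + ("alp", "ati", "non_gluten")}
    )
    peptide_cv: float = 0.15
    response_sigma: float = 0.30
    protein_sigma: float = 0.50
    base_abundance: float = 1.0e6
    transition_split: tuple = (0.5, 0.3, 0.2)
    special_peptides: tuple = ()
    extra_epitopes: tuple = ()  # (sequence, category, source) rows with no planted match
    solve_for_net: str | None = None  # group whose baseline is solved for net_gluten
    targets: ScenarioTargets | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per sample")
        if self.peptide_cv < 0:
            raise ValueError("peptide_cv must be >= 0")
        for g, r in self.baseline_ratios.items():
            if r is not None and r <= 0:
                raise ValueError(f"baseline ratio for {g} must be positive")


# The printed-value scenario. Epitope-bearing peptides are fully tryptic
# (end in K/R, no internal cleavage site) and each lives in its own
# carrier protein so its GW:MW ratio is independently assignable. The
# category composition mirrors the study: six coeliac HLA-DQ epitope
# cores spread over 25 peptides, twelve baker's-asthma peptides, ten
# wheat-allergy peptides (seven of them carrying a BA epitope as well,
# as HMW-glutenin repeat epitopes do), and a single WDEIA peptide.
_WDEIA_PEPTIDE = "QQQQQQQQILQQILQQQLIPCR"
_WDEIA_EPITOPE = "QILQQQLIPC"

#: Sollid-nomenclature DQ2.5 9-mer cores (alpha-, gamma-, omega-gliadin).
_CD_EPITOPES = (
    "PFPQPQLPY",  # glia-alpha1a
    "PQPQLPYPQ",  # glia-alpha2
    "PQQSFPQQQ",  # glia-gamma1
    "IQPQQPAQL",  # glia-gamma2
    "PFPQPQQPF",  # glia-omega1
    "PQPQQPFPW",  # glia-omega2
)
_BA_EPITOPES = ("GQQGYYPTS", "CQQLADINN")
_WA_EPITOPES = ("QQPGQGQQ", "QQSGQGQQ")

#: Hosts of the 25 coeliac-epitope peptides across the gliadin families.
_CD_HOSTS = ("alpha_gliadin",) * 10 + ("gamma_gliadin",) * 9 + ("omega_gliadin",) * 6


def _paper_specials() -> tuple[SpecialPeptide, ...]:
    specials = [
        SpecialPeptide(
            f"cd_{i + 1:02d}", _CD_HOSTS[i],
            ((_CD_EPITOPES[i % len(_CD_EPITOPES)], "CD_HLA_DQ"),),
        )
        for i in range(25)
    ]
    specials += [
        SpecialPeptide(
            f"bawa_{i + 1}", "ati",
            ((_BA_EPITOPES[i % 2], "BA"), (_WA_EPITOPES[(i // 2) % 2], "WA")),
        )
        for i in range(7)
    ]
    specials += [
        SpecialPeptide(f"ba_{i + 1}", "ati", ((_BA_EPITOPES[i % 2], "BA"),))
        for i in range(5)
    ]
    specials += [
        SpecialPeptide(f"wa_{i + 1}", "alp", ((_WA_EPITOPES[i % 2], "WA"),))
        for i in range(3)
    ]
    specials.append(
        SpecialPeptide(
            "wdeia", "omega_gliadin", ((_WDEIA_EPITOPE, "WDEIA"),),
            sequence=_WDEIA_PEPTIDE, ratio=0.177,
        )
    )
    return tuple(specials)


def paper_scenario(seed: int = 2021) -> ScenarioConfig:
    """The packaged scenario reproducing the study's printed aggregates."""
    return ScenarioConfig(
        seed=seed,
        background_proteins={
            "alpha_gliadin": 3,
            "gamma_gliadin": 3,
            "lmw_gs": 4,
            "hmw_gs": 4,
            "omega_gliadin": 3,
            "alp": 3,
            "ati": 3,
            "non_gluten": 2,
        },
        baseline_ratios={
            "alpha_gliadin": 0.50,
            "gamma_gliadin": 0.55,
            "lmw_gs": None,  # solved so net canonical gluten = 67%
            "hmw_gs": 1.30,
            "omega_gliadin": None,  # solved so the omega family sits at 100%
            "alp": 0.45,
            "ati": 1.40,
            "non_gluten": 1.0,
        },
        special_peptides=_paper_specials(),
        extra_epitopes=(
            ("QQPFP", "R5", "R5 mAb motif"),
            ("QPQLPY", "G12", "G12 mAb motif"),
        ),
        solve_for_net="lmw_gs",
        targets=ScenarioTargets(
            net_gluten=0.67,
            group_ratios={"omega_gliadin": 1.0},
            category_ratios={
                "CD_HLA_DQ": 0.67,
                "BA": 1.80,
                "WA": 3.79,
                "WDEIA": 0.177,
            },
            allergy_total=1.535,
        ),
    )


# ---------------------------------------------------------------------------
# proteome construction


@dataclass
class MonitoredPeptide:
    sequence: str
    protein_id: str
    group: str
    protease: str
    special: str | None = None  # name of the SpecialPeptide, if any


@dataclass
class SyntheticProteome:
    proteins: list
    overrides: dict
    monitored: list


def _scenario_epitopes(config: ScenarioConfig) -> list[Epitope]:
    out: list[Epitope] = []
    seen = set()
    for sp in config.special_peptides:
        for seq, cat in sp.epitopes:
            if (seq, cat) not in seen:
                seen.add((seq, cat))
                out.append(Epitope(seq, cat, f"planted:{sp.name}"))
    for seq, cat, src in config.extra_epitopes:
        if (seq, cat) not in seen:
            seen.add((seq, cat))
            out.append(Epitope(seq, cat, src))
    return out


def _filler_unit(rng, forbidden: list[str], used: set[str]) -> str:
    """A random tryptic unit: no internal K/R, ends K/R, epitope-free."""
    for _ in range(1000):
        length = int(rng.integers(8, 17))
        body = "".join(rng.choice(_FILLER_ALPHABET, size=length - 1))
        if body[0] == "P":  # would suppress the preceding cleavage
            body = "Q" + body[1:]
        unit = body + ("K" if rng.random() < 0.5 else "R")
        if unit in used:
            continue
        if any(f in unit for f in forbidden):
            continue
        used.add(unit)
        return unit
    raise RuntimeError("could not generate an epitope-free filler unit")


def _synthesize_special(
    rng,
    sp: SpecialPeptide,
    cats_of_seq: dict[str, set[str]],
    extra_cats: set[str],
    used: set[str],
) -> str:
    """Epitope core(s) plus random tryptic-clean flanks, 6-30 residues.

    Rejected and redrawn if the candidate contains an epitope of a
    category it was not designed for (untargeted antibody motifs such
    as G12 excepted), so planted category memberships stay exact.
    """
    cores = [seq for seq, _cat in sp.epitopes]
    designed = {cat for _seq, cat in sp.epitopes}
    room = 30 - sum(len(c) for c in cores) - 1  # final K/R takes one slot
    if room < 1:
        raise ValueError(f"special peptide {sp.name} cannot fit its epitopes")
    for _ in range(1000):
        n_pre = int(rng.integers(1, min(4, room) + 1))
        n_post = int(rng.integers(0, max(1, room - n_pre) + 1))
        pre = "".join(rng.choice(_FILLER_ALPHABET, size=n_pre))
        if pre[0] == "P":
            pre = "Q" + pre[1:]
        post = "".join(rng.choice(_FILLER_ALPHABET, size=n_post))
        pep = pre + "".join(cores) + post + ("K" if rng.random() < 0.5 else "R")
        if len(pep) > 30 or pep in used:
            continue
        hit_cats: set[str] = set()
        for seq, cats in cats_of_seq.items():
            if seq in pep:
                hit_cats |= cats
        if hit_cats - extra_cats != designed:
            continue
        used.add(pep)
        return pep
    raise RuntimeError(f"could not synthesize special peptide {sp.name}")


def generate_proteome(config: ScenarioConfig) -> SyntheticProteome:
    """Build the synthetic protein database and pick monitored peptides.

    Every protein is a concatenation of fully tryptic units (each ends
    in K/R, never starts with P, no internal cleavage site), so the
    tryptic digest recovers the units exactly. Background proteins
    contribute their first ``peptides_per_background_protein`` units to
    the monitored set plus, where available, one unique chymotryptic
    product; each special peptide is flanked by unmonitored fillers in
    a dedicated carrier protein. Deterministic for a given seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    scenario_epis = _scenario_epitopes(config)
    epitope_seqs = [e.sequence for e in scenario_epis]
    cats_of_seq: dict[str, set[str]] = {}
    for e in scenario_epis:
        cats_of_seq.setdefault(e.sequence, set()).add(e.category)
    extra_cats = {cat for _seq, cat, _src in config.extra_epitopes}
    used_units: set[str] = set()
    proteins: list[ProteinRecord] = []
    overrides: dict[str, str] = {}
    monitored: list[MonitoredPeptide] = []

    for sp in config.special_peptides:
        if sp.sequence is None:
            seq = _synthesize_special(rng, sp, cats_of_seq, extra_cats, used_units)
        else:
            seq = sp.sequence
            used_units.add(seq)
        if not 6 <= len(seq) <= 30:
            raise ValueError(f"special peptide {sp.name} outside the 6-30 aa window")
        for epi, _cat in sp.epitopes:
            if epi not in seq:
                raise ValueError(f"special peptide {sp.name} cannot host epitope {epi}")
        pid = f"SYN_{sp.group.upper()}_{sp.name.upper()}"
        units = [
            _filler_unit(rng, epitope_seqs, used_units),
            seq,
            _filler_unit(rng, epitope_seqs, used_units),
        ]
        proteins.append(
            ProteinRecord(pid, f"{pid} synthetic {sp.group} carrier of {sp.name}",
                          "".join(units), sp.group)
        )
        overrides[pid] = sp.group
        monitored.append(MonitoredPeptide(seq, pid, sp.group, "trypsin", sp.name))

    for group, count in config.background_proteins.items():
        for i in range(count):
            pid = f"SYN_{group.upper()}_BG{i + 1}"
            n_units = config.peptides_per_background_protein + 1
            units = [_filler_unit(rng, epitope_seqs, used_units) for _ in range(n_units)]
            proteins.append(
                ProteinRecord(pid, f"{pid} synthetic {group} background", "".join(units), group)
            )
            overrides[pid] = group
            for unit in units[: config.peptides_per_background_protein]:
                monitored.append(MonitoredPeptide(unit, pid, group, "trypsin"))

    if config.include_chymotryptic:
        chymo = DigestionRules.chymotrypsin()
        already = {m.sequence for m in monitored}
        all_seqs = [p.sequence for p in proteins]
        for prot in proteins:
            if not prot.id.split("_")[-1].startswith("BG"):
                continue
            products = filter_candidates([p for p, _, _ in digest(prot.sequence, chymo)])
            for pep in products:
                if pep in already:
                    continue
                if any(e in pep for e in epitope_seqs):
                    continue
                owners = sum(1 for s in all_seqs if pep in s)
                if owners != 1:
                    continue
                monitored.append(
                    MonitoredPeptide(pep, prot.id, prot.group, "chymotrypsin")
                )
                already.add(pep)
                break

    _verify_proteome(proteins, monitored, epitope_seqs, config)
    return SyntheticProteome(proteins, overrides, monitored)


def _verify_proteome(proteins, monitored, epitope_seqs, config) -> None:
    """Hard checks: unique mapping and exact category placement.

    Epitopes of one category may overlap inside a designed peptide (the
    CD 9-mer cores do), so what must match exactly is the set of
    epitope *categories* a monitored peptide contributes to: the
    designed set for special peptides (antibody-motif extras like
    R5/G12 tolerated), the empty set for background peptides.
    """
    cats_of_seq: dict[str, set[str]] = {}
    for e in _scenario_epitopes(config):
        cats_of_seq.setdefault(e.sequence, set()).add(e.category)
    designed = {
        sp.name: {cat for _seq, cat in sp.epitopes} for sp in config.special_peptides
    }
    extra_cats = {cat for _seq, cat, _src in config.extra_epitopes}
    for m in monitored:
        owners = {p.id for p in proteins if m.sequence in p.sequence}
        if owners != {m.protein_id}:
            raise RuntimeError(
                f"monitored peptide {m.sequence} maps to {owners}, expected {m.protein_id}"
            )
        hit_cats: set[str] = set()
        for seq in epitope_seqs:
            if seq in m.sequence:
                hit_cats |= cats_of_seq[seq]
        want = designed.get(m.special, set())
        if (hit_cats - extra_cats if m.special else hit_cats) != want:
            raise RuntimeError(
                f"epitope categories violated for {m.sequence}: "
                f"found {sorted(hit_cats)}, planted {sorted(want)}"
            )


# ---------------------------------------------------------------------------
# ratio solving


def _weight(r: float) -> float:
    return 1.0 / (1.0 + r)


def _solve_ratios(config: ScenarioConfig, monitored: list) -> dict[str, float]:
    """Per-special and per-group true GW/MW ratios honouring the targets.

    Returns a mapping {special name or group label -> ratio}. Uses the
    identity ratio = (n - W)/W, W = sum 1/(1+r_i), of the normalized-sum
    estimand; every equation is linear in one unknown weight, so the
    solution is closed-form.
    """
    ratios: dict[str, float] = {}
    for g, r in config.baseline_ratios.items():
        if r is not None:
            ratios[g] = float(r)
    for sp in config.special_peptides:
        if sp.ratio is not None:
            ratios[sp.name] = float(sp.ratio)

    t = config.targets
    if t is None:
        unsolved = [g for g, r in config.baseline_ratios.items() if r is None]
        if unsolved or any(sp.ratio is None for sp in config.special_peptides):
            raise ValueError("ratios left unsolved but no targets given")
        return ratios

    # category membership of special peptides (by special name)
    cat_members: dict[str, list] = {}
    for sp in config.special_peptides:
        for _seq, cat in sp.epitopes:
            if sp.name not in cat_members.setdefault(cat, []):
                cat_members[cat].append(sp.name)

    # 1. categories without a cross-category shared member: every free
    #    member takes the category ratio directly
    shared = {
        name
        for cat, names in cat_members.items()
        if cat in t.category_ratios
        for name in names
        if sum(name in ns for c2, ns in cat_members.items() if c2 in t.category_ratios) > 1
    }
    for cat, target in t.category_ratios.items():
        names = cat_members.get(cat, [])
        if any(n in shared for n in names):
            continue  # handled by the combined-total solve below
        for name in names:
            if name not in ratios:
                ratios[name] = float(target)

    # 2. the combined allergy total pins the shared BA/WA peptide weight
    if t.allergy_total is not None:
        allergy_cats = [c for c in ("BA", "WA", "WDEIA") if c in cat_members]
        union = []
        for c in allergy_cats:
            for name in cat_members[c]:
                if name not in union:
                    union.append(name)
        w_union_target = len(union) / (1.0 + t.allergy_total)
        w_cats = sum(
            len(cat_members[c]) / (1.0 + t.category_ratios[c]) for c in allergy_cats
        )
        shared_allergy = sorted(
            n for n in shared if any(n in cat_members[c] for c in allergy_cats)
        )
        if not shared_allergy:
            raise ValueError(
                "planting an exact combined allergy total needs at least one "
                "peptide shared between two allergy categories"
            )
        # each shared peptide sits in exactly two categories, so the
        # union weight removes their weights once; split equally
        w_shared_total = w_cats - w_union_target
        w_each = w_shared_total / len(shared_allergy)
        if not 0.0 < w_each < 1.0:
            raise ValueError(f"infeasible shared-peptide weight {w_each:.4f}")
        for name in shared_allergy:
            ratios[name] = 1.0 / w_each - 1.0
        # 3. remaining members of each category absorb the residual weight
        for cat in allergy_cats:
            names = cat_members[cat]
            w_target = len(names) / (1.0 + t.category_ratios[cat])
            fixed = [n for n in names if n in ratios]
            free = [n for n in names if n not in ratios]
            if not free:
                continue
            w_rest = w_target - sum(_weight(ratios[n]) for n in fixed)
            if not 0.0 < w_rest / len(free) < 1.0:
                raise ValueError(f"infeasible residual weight for category {cat}")
            for n in free:
                ratios[n] = len(free) / w_rest - 1.0

    group_counts: dict[str, dict[str, int]] = {}
    for m in monitored:
        key = m.special if m.special else m.group
        group_counts.setdefault(m.group, {}).setdefault(key, 0)
        group_counts[m.group][key] += 1

    # 4. groups pinned to their own target ratio (e.g. omega at 1.0)
    for group, target in t.group_ratios.items():
        if config.baseline_ratios.get(group) is not None:
            continue
        counts = group_counts.get(group, {})
        n_tot = sum(counts.values())
        w_target = n_tot / (1.0 + target)
        w_fixed = sum(
            c * _weight(ratios[k]) for k, c in counts.items() if k != group
        )
        n_free = counts.get(group, 0)
        if n_free == 0:
            raise ValueError(f"no free background peptides in group {group}")
        r = n_free / (w_target - w_fixed) - 1.0
        if r <= 0:
            raise ValueError(f"infeasible solved ratio for group {group}: {r:.4f}")
        ratios[group] = r

    # 5. one canonical group's baseline absorbs the net-gluten target
    if config.solve_for_net is not None:
        gsolve = config.solve_for_net
        N_c = W_fixed = 0.0
        for group in CANONICAL_GLUTEN_GROUPS:
            counts = group_counts.get(group, {})
            N_c += sum(counts.values())
            for key, c in counts.items():
                if group == gsolve and key == gsolve:
                    continue
                W_fixed += c * _weight(ratios[key])
        n_free = group_counts.get(gsolve, {}).get(gsolve, 0)
        if n_free == 0:
            raise ValueError(f"no free background peptides in group {gsolve}")
        W_target = N_c / (1.0 + t.net_gluten)
        r = n_free / (W_target - W_fixed) - 1.0
        if r <= 0:
            raise ValueError(f"infeasible net-gluten solve for {gsolve}: {r:.4f}")
        ratios[gsolve] = r

    missing = [g for g, r in config.baseline_ratios.items() if r is None and g not in ratios]
    missing += [sp.name for sp in config.special_peptides if sp.name not in ratios]
    if missing:
        raise ValueError(f"unsolved ratios remain: {missing}")
    return ratios


# ---------------------------------------------------------------------------
# quantitative table and truth manifest


@dataclass
class TruthManifest:
    protein_truth: pd.DataFrame  # id, group, mw_abundance, gw_abundance, ratio
    peptide_truth: pd.DataFrame  # sequence, protein, group, protease, truths, categories
    group_ratios: dict
    net_gluten_ratio: float
    category_ratios: dict

    def to_json(self, path) -> None:
        payload = {
            "group_ratios": self.group_ratios,
            "net_gluten_ratio": self.net_gluten_ratio,
            "category_ratios": self.category_ratios,
            "protein_truth": self.protein_truth.to_dict(orient="records"),
            "peptide_truth": self.peptide_truth.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def truth_aggregates(peptide_truth: pd.DataFrame) -> tuple[dict, float, dict]:
    """Recompute group/category/net ratios from per-peptide truth.

    Applies the pipeline's own estimand: normalized sample means are
    2g/(g+m) and 2m/(g+m) per peptide, summed within a group/category.
    """
    g = peptide_truth["true_gw"].to_numpy(float)
    m = peptide_truth["true_mw"].to_numpy(float)
    ngw, nmw = 2 * g / (g + m), 2 * m / (g + m)
    group_ratios = {}
    groups_col = peptide_truth["group"].to_numpy()
    for group in sorted(set(groups_col)):
        mask = groups_col == group
        group_ratios[group] = float(ngw[mask].sum() / nmw[mask].sum())
    canon = peptide_truth["group"].isin(CANONICAL_GLUTEN_GROUPS).to_numpy()
    net = float(ngw[canon].sum() / nmw[canon].sum())
    cat_ratios: dict[str, float] = {}
    cats_col = peptide_truth["categories"].fillna("")
    all_cats = sorted({c for row in cats_col for c in row.split(";") if c})
    for cat in all_cats:
        mask = cats_col.str.split(";").apply(lambda cs: cat in cs).to_numpy()
        cat_ratios[cat] = float(ngw[mask].sum() / nmw[mask].sum())
    allergy = cats_col.str.split(";").apply(
        lambda cs: bool(set(cs) & {"BA", "WA", "WDEIA"})
    ).to_numpy()
    if allergy.any():
        cat_ratios["ALLERGY_TOTAL"] = float(ngw[allergy].sum() / nmw[allergy].sum())
    return group_ratios, net, cat_ratios


def generate_quant(
    config: ScenarioConfig, proteome: SyntheticProteome
) -> tuple[pd.DataFrame, TruthManifest]:
    """Replicate-level transition peak areas plus the truth manifest.

    Peptide true mean area = protein abundance x a per-peptide
    log-normal response factor (identical in both samples, so the
    protein's GW:MW ratio carries through); replicate area = true mean
    x log-normal noise with coefficient of variation ``peptide_cv``
    (exact at cv = 0); transition areas split the peptide area in the
    fixed ``transition_split`` proportions.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    ratios = _solve_ratios(config, proteome.monitored)

    prot_rows = []
    prot_abundance: dict[str, tuple[float, float]] = {}
    special_by_pid = {
        f"SYN_{sp.group.upper()}_{sp.name.upper()}": sp for sp in config.special_peptides
    }
    for prot in proteome.proteins:
        mw = config.base_abundance * float(
            np.exp(rng.normal(0.0, config.protein_sigma))
        )
        sp = special_by_pid.get(prot.id)
        ratio = ratios[sp.name] if sp else ratios[prot.group]
        gw = mw * ratio
        prot_abundance[prot.id] = (gw, mw)
        prot_rows.append(
            {"id": prot.id, "group": prot.group, "gw_abundance": gw,
             "mw_abundance": mw, "ratio": ratio}
        )

    split = np.asarray(config.transition_split, float)
    split = split / split.sum()
    sigma = float(np.sqrt(np.log1p(config.peptide_cv**2)))
    replicates = [("GW", f"GW_{i + 1}") for i in range(config.n_replicates)] + [
        ("MW", f"MW_{i + 1}") for i in range(config.n_replicates)
    ]

    pep_rows, quant_rows = [], []
    for m in proteome.monitored:
        gw_p, mw_p = prot_abundance[m.protein_id]
        response = float(np.exp(rng.normal(0.0, config.response_sigma)))
        true_gw, true_mw = gw_p * response, mw_p * response
        cats = ""
        if m.special:
            sp = next(s for s in config.special_peptides if s.name == m.special)
            cats = ";".join(sorted({c for _seq, c in sp.epitopes}))
        pep_rows.append(
            {"sequence": m.sequence, "protein_id": m.protein_id, "group": m.group,
             "protease": m.protease, "true_gw": true_gw, "true_mw": true_mw,
             "ratio": true_gw / true_mw, "categories": cats}
        )
        for sample, rep in replicates:
            true_mean = true_gw if sample == "GW" else true_mw
            if config.peptide_cv > 0:
                noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            else:
                noise = 1.0
            area = true_mean * noise
            for t, frac in enumerate(split, start=1):
                quant_rows.append(
                    {"peptide": m.sequence, "protease": m.protease,
                     "replicate": rep, "sample": sample,
                     "transition": f"t{t}", "area": area * frac}
                )

    peptide_truth = pd.DataFrame.from_records(pep_rows)
    group_ratios, net, cat_ratios = truth_aggregates(peptide_truth)
    manifest = TruthManifest(
        pd.DataFrame.from_records(prot_rows), peptide_truth,
        group_ratios, net, cat_ratios,
    )
    _check_targets(config, manifest)
    return pd.DataFrame.from_records(quant_rows), manifest


def _check_targets(config: ScenarioConfig, manifest: TruthManifest) -> None:
    t = config.targets
    if t is None:
        return
    tol = 1e-9
    assert abs(manifest.net_gluten_ratio - t.net_gluten) < tol
    for g, target in t.group_ratios.items():
        assert abs(manifest.group_ratios[g] - target) < tol
    for c, target in t.category_ratios.items():
        assert abs(manifest.category_ratios[c] - target) < tol
    if t.allergy_total is not None:
        assert abs(manifest.category_ratios["ALLERGY_TOTAL"] - t.allergy_total) < tol


# ---------------------------------------------------------------------------
# one-call scenario run and file output


@dataclass
class ScenarioRun:
    config: ScenarioConfig
    proteome: SyntheticProteome
    quant: pd.DataFrame
    manifest: TruthManifest
    epitopes: list

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "proteome.fasta", "w") as fh:
            for p in self.proteome.proteins:
                fh.write(f">{p.id} {p.description}\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i : i + 60] + "\n")
        with open(out / "overrides.tsv", "w") as fh:
            fh.write("protein_id\tgroup\n")
            for pid, group in self.proteome.overrides.items():
                fh.write(f"{pid}\t{group}\n")
        self.quant.to_csv(out / "quant.csv", index=False, float_format="%.6f")
        with open(out / "epitopes.tsv", "w") as fh:
            fh.write("sequence\tcategory\tsource_id\n")
            for e in self.epitopes:
                fh.write(f"{e.sequence}\t{e.category}\t{e.source_id}\n")
        self.manifest.to_json(out / "manifest.json")
        cfg = asdict(self.config)
        cfg["special_peptides"] = [asdict(sp) for sp in self.config.special_peptides]
        if self.config.targets is not None:
            cfg["targets"] = asdict(self.config.targets)
        with open(out / "scenario.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def generate_scenario(config: ScenarioConfig) -> ScenarioRun:
    proteome = generate_proteome(config)
    quant, manifest = generate_quant(config, proteome)
    return ScenarioRun(config, proteome, quant, manifest, _scenario_epitopes(config))
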