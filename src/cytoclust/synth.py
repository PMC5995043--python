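"""Synthetic mass-cytometry study generator.

Emulates the structure of a three-condition HIV immunophenotyping study
(primary infection, treated infection, healthy donors; six subjects each):
per-sample event tables over a CyTOF-style antibody panel, a sample sheet
with an HIV-DNA covariate, and full ground truth (per-event population
labels, realized abundances, planted effect sizes).

Generative model, per sample:

* population mixture: condition-specific base abundances, perturbed per
  sample by logistic-normal noise with a stated coefficient of variation,
  then realized by a multinomial draw;
* marker intensities on the arcsinh-transformed scale: with probability
  ``pi_pos`` the positive component ``N(mu_pos, sigma)``, otherwise the
  negative/background component ``N(0.3, 0.25)``; values are mapped back to
  raw dual counts by the inverse transform and floored at zero (this floor
  produces the zero inflation typical of CyTOF negatives);
* artifacts: normalization beads (high Ce140, near-zero DNA), dead cells
  (high Rhodium viability stain), and doublets (channel-wise sum of two
  cell events, hence doubled DNA-intercalator signal);
* optional multiplicative acquisition drift (signal ramp over the event
  index) to exercise windowed bead normalization.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ChannelDef, EventTable, Panel, SampleSheet

__all__ = [
    "MarkerProfile",
    "PopulationSpec",
    "PlantedDAC",
    "PlantedCC",
    "StudyDesign",
    "StudyTruth",
    "SyntheticStudy",
    "InvalidDesignError",
    "generate_sample",
    "generate_study",
    "tiny_design",
    "paper_like_design",
    "null_design",
]

# background (negative) component on the transformed scale: typical CyTOF
# unstained-channel signal after arcsinh(x/5)
MU_NEG = 0.3
SIGMA_NEG = 0.25
DEFAULT_COFACTOR = 5.0

# intensities of the structural channels (transformed scale)
DNA_MU, DNA_SIGMA = 3.8, 0.15
BEAD_MU, BEAD_SIGMA = 4.5, 0.2
DEAD_MU, DEAD_SIGMA = 3.5, 0.2
BEAD_DNA_MU, BEAD_DNA_SIGMA = 0.05, 0.03


class InvalidDesignError(ValueError):
    """The study design violates one of its invariants."""


@dataclass(frozen=True)
class MarkerProfile:
    """Positive-component parameters of one marker in one population."""

    mu_pos: float
    sigma: float
    pi_pos: float

    def validate(self, where: str) -> None:
        if self.sigma <= 0:
            raise InvalidDesignError(f"{where}: sigma must be > 0")
        if not 0.0 <= self.pi_pos <= 1.0:
            raise InvalidDesignError(f"{where}: pi_pos must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """A cell population: marker profile plus per-condition abundance.

    Markers absent from ``profile`` are background-only (pi_pos = 0).
    ``base_abundance`` maps condition -> fraction of non-artifact events.
    """

    name: str
    profile: Mapping[str, MarkerProfile]
    base_abundance: Mapping[str, float]

    def validate(self) -> None:
        for marker, prof in self.profile.items():
            prof.validate(f"population {self.name}, marker {marker}")
        for cond, a in self.base_abundance.items():
            if not 0.0 <= a <= 1.0:
                raise InvalidDesignError(
                    f"population {self.name}: abundance for {cond} outside [0, 1]"
                )


@dataclass(frozen=True)
class PlantedDAC:
    population: str
    condition_pair: tuple[str, str]
    fold_change: float


@dataclass(frozen=True)
class PlantedCC:
    population: str
    target_r: float
    covariate_name: str = "hiv_dna_log10"


@dataclass
class StudyDesign:
    conditions: Sequence[str]
    populations: Sequence[PopulationSpec]
    panel: Panel
    subjects_per_condition: int = 6
    events_per_sample: int = 5000
    planted_dacs: Sequence[PlantedDAC] = ()
    planted_cc: PlantedCC | None = None
    artifact_rates: tuple[float, float, float] = (0.02, 0.03, 0.03)  # bead, dead, doublet
    abundance_cv: float = 0.2
    signal_drift: float = 0.0  # multiplicative ramp 1 -> 1+drift over acquisition
    cofactor: float = DEFAULT_COFACTOR
    #: conditions whose samples carry covariate 0 (undetectable HIV DNA)
    uninfected_conditions: Sequence[str] = ("healthy",)
    seed: int = 0

    def validate(self) -> None:
        if self.events_per_sample < 1:
            raise InvalidDesignError("events_per_sample must be >= 1")
        if self.subjects_per_condition < 1:
            raise InvalidDesignError("subjects_per_condition must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise InvalidDesignError("duplicate conditions")
        if not 0.0 <= self.abundance_cv:
            raise InvalidDesignError("abundance_cv must be >= 0")
        for frac in self.artifact_rates:
            if not 0.0 <= frac < 1.0:
                raise InvalidDesignError("artifact fractions must be in [0, 1)")
        if sum(self.artifact_rates) >= 1.0:
            raise InvalidDesignError("artifact fractions sum to >= 1")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise InvalidDesignError("duplicate population names")
        for pop in self.populations:
            pop.validate()
        for cond in self.conditions:
            total = sum(p.base_abundance.get(cond, 0.0) for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise InvalidDesignError(
                    f"abundances for condition {cond!r} sum to {total}, not 1"
                )
        by_name = {p.name: p for p in self.populations}
        for dac in self.planted_dacs:
            if dac.fold_change <= 0:
                raise InvalidDesignError("fold_change must be > 0")
            pop = by_name.get(dac.population)
            if pop is None:
                raise InvalidDesignError(f"planted DAC names unknown population {dac.population!r}")
            a, b = dac.condition_pair
            ratio = pop.base_abundance.get(a, 0.0) / pop.base_abundance.get(b, np.nan)
            if not np.isclose(ratio, dac.fold_change, rtol=1e-6):
                raise InvalidDesignError(
                    f"planted DAC for {dac.population!r}: base abundances give fold change "
                    f"{ratio:.4g}, declared {dac.fold_change}"
                )
        if self.planted_cc is not None:
            if not -1.0 < self.planted_cc.target_r < 1.0:
                raise InvalidDesignError("target_r must be in (-1, 1)")
            if self.planted_cc.population not in by_name:
                raise InvalidDesignError(
                    f"planted CC names unknown population {self.planted_cc.population!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_s{subject + 1}"
            for cond in self.conditions
            for subject in range(self.subjects_per_condition)
        ]


@dataclass
class StudyTruth:
    """Ground truth of one synthetic study."""

    labels: dict[str, np.ndarray]  # sample_id -> per-event label (population or artifact)
    abundances: pd.DataFrame  # populations x samples, fractions of non-artifact events
    covariate: pd.Series  # per sample
    planted_dacs: list[dict]
    planted_cc: dict | None

    ARTIFACT_LABELS = ("bead", "dead", "doublet")

    def realized_fold_change(self, population: str, pair: tuple[str, str],
                             sheet: SampleSheet) -> float:
        a = self.abundances.loc[population, sheet.samples_in(pair[0])].mean()
        b = self.abundances.loc[population, sheet.samples_in(pair[1])].mean()
        return float(a / b)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": {s: list(map(str, v)) for s, v in self.labels.items()},
                "abundances": {
                    s: self.abundances[s].to_dict() for s in self.abundances.columns
                },
                "covariate": self.covariate.to_dict(),
                "planted_dacs": self.planted_dacs,
                "planted_cc": self.planted_cc,
            },
            indent=0,
        )

    @classmethod
    def from_json(cls, text: str) -> "StudyTruth":
        d = json.loads(text)
        ab = pd.DataFrame(d["abundances"])
        ab.index.name = "population"
        return cls(
            labels={s: np.array(v, dtype=object) for s, v in d["labels"].items()},
            abundances=ab,
            covariate=pd.Series(d["covariate"], name="hiv_dna_log10"),
            planted_dacs=d["planted_dacs"],
            planted_cc=d["planted_cc"],
        )


@dataclass
class SyntheticStudy:
    design: StudyDesign
    tables: list[EventTable]
    sheet: SampleSheet
    panel: Panel
    truth: StudyTruth


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _perturb_abundances(base: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal perturbation with coefficient of variation ``cv``.

    Multiplies each fraction by a lognormal factor and renormalizes, which
    keeps the vector in the simplex (Dirichlet-equivalent noise).
    """
    if cv <= 0:
        return base.copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    factors = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=base.size)
    out = base * factors
    return out / out.sum()


def _draw_marker_block(n: int, panel: Panel, profile: Mapping[str, MarkerProfile],
                       rng: np.random.Generator) -> np.ndarray:
    """Transformed-scale intensities for n events of one population."""
    k = len(panel)
    out = rng.normal(MU_NEG, SIGMA_NEG, size=(n, k))
    for j, ch in enumerate(panel.channels):
        if ch.role == "dna":
            out[:, j] = rng.normal(DNA_MU, DNA_SIGMA, size=n)
        elif ch.role in ("bead", "viability"):
            continue  # background unless the event is an artifact
        else:
            prof = profile.get(ch.marker)
            if prof is not None and prof.pi_pos > 0:
                pos = rng.random(n) < prof.pi_pos
                out[pos, j] = rng.normal(prof.mu_pos, prof.sigma, size=int(pos.sum()))
    return out


def _to_raw(transformed: np.ndarray, cofactor: float) -> np.ndarray:
    return np.maximum(np.sinh(transformed) * cofactor, 0.0)


def generate_sample(design: StudyDesign, condition: str, subject: int,
                    seed: int) -> tuple[EventTable, dict]:
    """Generate one sample's raw-count event table plus its truth slice.

    Returns ``(table, truth)`` where ``truth`` holds the per-event labels
    (population name, or ``bead``/``dead``/``doublet``) and the realized
    population abundances among non-artifact events.
    """
    design.validate()
    if condition not in design.conditions:
        raise InvalidDesignError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    panel = design.panel
    n = design.events_per_sample

    bead_f, dead_f, doublet_f = design.artifact_rates
    counts = rng.multinomial(n, [bead_f, dead_f, doublet_f,
                                 1.0 - bead_f - dead_f - doublet_f])
    n_bead, n_dead, n_doublet, n_cell = map(int, counts)

    base = np.array([p.base_abundance.get(condition, 0.0) for p in design.populations])
    fractions = _perturb_abundances(base, design.abundance_cv, rng)
    # dead cells and doublet halves are drawn from the same mixture
    pop_counts = rng.multinomial(n_cell + n_dead + 2 * n_doublet, fractions)

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for pop, c in zip(design.populations, pop_counts):
        if c == 0:
            continue
        blocks.append(_draw_marker_block(c, panel, pop.profile, rng))
        labels.extend([pop.name] * c)
    pool = np.vstack(blocks) if blocks else np.empty((0, len(panel)))
    order = rng.permutation(len(pool))
    pool = pool[order]
    pool_labels = np.array(labels, dtype=object)[order]

    raw = _to_raw(pool, design.cofactor)

    cells_raw = raw[:n_cell]
    cell_labels = pool_labels[:n_cell]

    dead_raw = raw[n_cell:n_cell + n_dead].copy()
    if n_dead:
        viab_col = panel.channel_ids.index(panel.viability_channel)
        dead_raw[:, viab_col] = _to_raw(
            rng.normal(DEAD_MU, DEAD_SIGMA, size=n_dead), design.cofactor)

    halves = raw[n_cell + n_dead:]
    doublet_raw = halves[:n_doublet] + halves[n_doublet:2 * n_doublet]

    bead_block = rng.normal(MU_NEG, SIGMA_NEG, size=(n_bead, len(panel)))
    for j, ch in enumerate(panel.channels):
        if ch.role == "bead":
            bead_block[:, j] = rng.normal(BEAD_MU, BEAD_SIGMA, size=n_bead)
        elif ch.role == "dna":
            bead_block[:, j] = rng.normal(BEAD_DNA_MU, BEAD_DNA_SIGMA, size=n_bead)
    bead_raw = _to_raw(bead_block, design.cofactor)

    values = np.vstack([cells_raw, dead_raw, doublet_raw, bead_raw])
    all_labels = np.concatenate([
        cell_labels,
        np.repeat("dead", n_dead),
        np.repeat("doublet", n_doublet),
        np.repeat("bead", n_bead),
    ]).astype(object)

    perm = rng.permutation(n)
    values = values[perm]
    all_labels = all_labels[perm]

    if design.signal_drift != 0.0:
        ramp = 1.0 + design.signal_drift * np.arange(n) / max(n - 1, 1)
        values = values * ramp[:, None]

    sample_id = f"{condition}_s{subject + 1}"
    table = EventTable(
        sample_id=sample_id,
        values=pd.DataFrame(values, columns=panel.channel_ids),
    )
    non_artifact = ~np.isin(all_labels.astype(str), StudyTruth.ARTIFACT_LABELS)
    denom = max(int(non_artifact.sum()), 1)
    realized = pd.Series(
        {p.name: float((all_labels[non_artifact] == p.name).sum()) / denom
         for p in design.populations},
        name=sample_id,
    )
    return table, {"labels": all_labels, "abundance": realized}


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

def _calibrate_covariate(abund: pd.Series, infected: pd.Series,
                         target_r: float, rng: np.random.Generator) -> pd.Series:
    """HIV-DNA-like covariate correlated with ``abund`` at expectation ``target_r``.

    Infected samples get an affine function of the population's realized
    abundance plus Gaussian noise; uninfected samples are pinned at 0
    (undetectable). The noise sd is solved from the moment identity
    E[corr] ~ rho0 * sqrt(Var(d) / (Var(d) + kappa * sigma^2)) computed on
    the exact covariate vector downstream analyses consume (zeros included),
    so that the plug-in expected Pearson coefficient equals target_r.
    """
    a = abund.to_numpy(float)
    inf = infected.to_numpy(bool)
    n = a.size
    a_inf = a[inf]
    # anchor the affine map so the mean healthy abundance lands on 0: the
    # pinned zeros then sit on the same line as the infected samples, and the
    # infected mean maps to ~3 log10 copies (treated donors intermediate,
    # primary infection highest)
    a_h = a[~inf].mean() if (~inf).any() else float(a.min())
    denom = a_inf.mean() - a_h
    if abs(denom) < 1e-12:
        denom = a_inf.std() if a_inf.std() > 0 else 1.0
    beta = 3.0 / denom
    if np.sign(beta) != np.sign(target_r):
        beta = -beta
    alpha = -beta * a_h
    d = np.where(inf, alpha + beta * a, 0.0)

    var_d = d.var()
    var_a = a.var()
    cov_da = np.cov(d, a, bias=True)[0, 1]
    rho0 = cov_da / np.sqrt(var_d * var_a) if var_d > 0 and var_a > 0 else 0.0
    kappa = (inf.mean()) * (1.0 - 1.0 / n)
    if abs(rho0) > abs(target_r) and kappa > 0:
        sigma2 = var_d * ((rho0 / target_r) ** 2 - 1.0) / kappa
        sigma = float(np.sqrt(max(sigma2, 0.0)))
    else:
        sigma = 0.0  # target unreachable: emit the noise-free covariate
    noise = rng.normal(0.0, sigma, size=n)
    c = np.where(inf, d + noise, 0.0)
    return pd.Series(c, index=abund.index, name="hiv_dna_log10")


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Generate every sample of the design plus sheet, panel and truth."""
    design.validate()
    root = np.random.SeedSequence(design.seed)
    sample_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                    root.spawn(len(design.sample_ids) + 1)]
    study_rng = np.random.default_rng(sample_seeds[-1])

    tables: list[EventTable] = []
    labels: dict[str, np.ndarray] = {}
    realized: list[pd.Series] = []
    i = 0
    for cond in design.conditions:
        for subject in range(design.subjects_per_condition):
            table, truth_slice = generate_sample(design, cond, subject, sample_seeds[i])
            tables.append(table)
            labels[table.sample_id] = truth_slice["labels"]
            realized.append(truth_slice["abundance"])
            i += 1
    abundances = pd.concat(realized, axis=1)
    abundances.index.name = "population"

    sample_ids = [t.sample_id for t in tables]
    conditions = [s.rsplit("_s", 1)[0] for s in sample_ids]
    subjects = [f"subj_{c}_{s.rsplit('_s', 1)[1]}" for c, s in zip(conditions, sample_ids)]
    infected = pd.Series(
        [c not in design.uninfected_conditions for c in conditions], index=sample_ids)

    planted_cc_truth: dict | None = None
    if design.planted_cc is not None:
        covariate = _calibrate_covariate(
            abundances.loc[design.planted_cc.population],
            infected, design.planted_cc.target_r, study_rng)
        r_realized = float(np.corrcoef(
            abundances.loc[design.planted_cc.population], covariate)[0, 1])
        planted_cc_truth = {
            "population": design.planted_cc.population,
            "covariate_name": design.planted_cc.covariate_name,
            "target_r": design.planted_cc.target_r,
            "realized_r": r_realized,
        }
    else:
        vals = np.where(infected.to_numpy(), study_rng.normal(3.0, 0.5, len(sample_ids)), 0.0)
        covariate = pd.Series(vals, index=sample_ids, name="hiv_dna_log10")

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subjects,
        "condition": conditions,
        "hiv_dna_log10": covariate.to_numpy(),
    }))

    planted_dac_truth = []
    truth = StudyTruth(labels=labels, abundances=abundances, covariate=covariate,
                       planted_dacs=planted_dac_truth, planted_cc=planted_cc_truth)
    for dac in design.planted_dacs:
        planted_dac_truth.append({
            "population": dac.population,
            "condition_pair": list(dac.condition_pair),
            "fold_change": dac.fold_change,
            "realized_fold_change": truth.realized_fold_change(
                dac.population, dac.condition_pair, sheet),
        })
    return SyntheticStudy(design=design, tables=tables, sheet=sheet,
                          panel=design.panel, truth=truth)


# ---------------------------------------------------------------------------
# default panels and designs
# ---------------------------------------------------------------------------

_STRUCTURAL = [
    ChannelDef("Ir191", "DNA1", "dna"),
    ChannelDef("Ir193", "DNA2", "dna"),
    ChannelDef("Rh103", "Viability", "viability"),
    ChannelDef("Ce140", "Bead", "bead"),
]

_GATING = ["CD45", "CD3", "CD19", "CD4", "CD8"]

_CLUSTERING_FULL = [
    "CD32a", "CCR7", "CD45RA", "CD57", "NKG2C", "LILRA2", "LILRB1", "CD64",
    "CD38", "HLA-DR", "HLA-I", "CD14", "CD25", "CD27", "CD28", "CD127",
    "PD1", "CCR5", "CD69", "CD161", "CD56", "CD16", "ICOS", "CD95", "CD36",
]

# enough metals for the 35-channel panel
_METALS = [
    "Y89", "In115", "La139", "Pr141", "Nd142", "Nd143", "Nd144", "Nd145",
    "Nd146", "Sm147", "Nd148", "Sm149", "Sm150", "Eu151", "Sm152", "Eu153",
    "Sm154", "Gd155", "Gd156", "Gd158", "Tb159", "Gd160", "Dy161", "Dy162",
    "Dy163", "Dy164", "Ho165", "Er166", "Er167", "Er168", "Tm169", "Er170",
    "Yb171", "Yb172", "Yb173", "Yb174", "Lu175", "Yb176",
]


def make_panel(clustering: Sequence[str], excluded: Sequence[str] = ("CX3CR1",)) -> Panel:
    """Panel with the structural channels, the five gating markers, the given
    clustering markers, and markers acquired but excluded from clustering."""
    defs = list(_STRUCTURAL)
    metals = iter(_METALS)
    for m in _GATING:
        defs.append(ChannelDef(next(metals), m, "gating"))
    for m in clustering:
        defs.append(ChannelDef(next(metals), m, "clustering"))
    for m in excluded:
        defs.append(ChannelDef(next(metals), m, "excluded"))
    return Panel(defs)


def _pos(mu: float = 3.5, sigma: float = 0.35, pi: float = 1.0) -> MarkerProfile:
    return MarkerProfile(mu_pos=mu, sigma=sigma, pi_pos=pi)


def _lineage(*markers: str, **extra: MarkerProfile) -> dict[str, MarkerProfile]:
    prof = {m: _pos() for m in markers}
    prof.update(extra)
    return prof


def _cd4_base(**markers: MarkerProfile) -> dict[str, MarkerProfile]:
    """CD45+ CD3+ CD4+ T-cell core phenotype."""
    return _lineage("CD45", "CD3", "CD4", **markers)


def _const(x: float, conditions: Sequence[str]) -> dict[str, float]:
    return {c: x for c in conditions}


def paper_like_design(seed: int = 0, events_per_sample: int = 5000,
                      subjects_per_condition: int = 6) -> StudyDesign:
    """Three conditions x six subjects, 35-channel panel, a planted
    CD32a+ LILRA2+ CD57+ NKG2C+ activated effector/memory population that is
    4-fold more abundant in primary infection than in healthy donors and is
    linked to the HIV-DNA covariate at target r = 0.9."""
    conds = ("primary_HIV", "HIV_cART", "healthy")
    panel = make_panel(_CLUSTERING_FULL)
    planted_ab = {"primary_HIV": 0.032, "HIV_cART": 0.016, "healthy": 0.008}
    filler_ab = {c: 1.0 - 0.79 - planted_ab[c] for c in conds}  # naive CD4 absorbs
    pops = [
        PopulationSpec("b_cells", _lineage("CD45", "CD19", "HLA-DR"), _const(0.08, conds)),
        PopulationSpec("cd8_t", _lineage("CD45", "CD3", "CD8"), _const(0.18, conds)),
        PopulationSpec("monocytes",
                       _lineage("CD45", "CD14", "HLA-DR", "CD64",
                                CD32a=_pos(4.0), CD36=_pos()),
                       _const(0.10, conds)),
        PopulationSpec("nk_cells", _lineage("CD45", "CD56", "CD16", NKG2C=_pos(pi=0.3)),
                       _const(0.06, conds)),
        PopulationSpec("cd4_naive", _cd4_base(CCR7=_pos(), CD45RA=_pos(),
                                              CD27=_pos(), CD28=_pos(), CD127=_pos()),
                       filler_ab),
        PopulationSpec("cd4_cm", _cd4_base(CCR7=_pos(), CD27=_pos(), CD28=_pos(),
                                           CD127=_pos(), CD95=_pos(pi=0.6)),
                       _const(0.16, conds)),
        PopulationSpec("cd4_effmem", _cd4_base(CD95=_pos(), CCR5=_pos(pi=0.5),
                                               PD1=_pos(pi=0.4), CD28=_pos(pi=0.5)),
                       _const(0.12, conds)),
        PopulationSpec("cd4_treg", _cd4_base(CD25=_pos(), ICOS=_pos(pi=0.5)),
                       _const(0.05, conds)),
        PopulationSpec("cd4_cm_cd32", _cd4_base(CCR7=_pos(), CD27=_pos(),
                                                CD32a=_pos(3.5), LILRB1=_pos(pi=0.3)),
                       _const(0.04, conds)),
        PopulationSpec(
            "cd4_effmem_cd32_act",
            _cd4_base(CD32a=_pos(4.5), LILRA2=_pos(), CD57=_pos(4.0), NKG2C=_pos(),
                      CD38=_pos(), **{"HLA-I": _pos(4.0)}, CD64=_pos(pi=0.5),
                      LILRB1=_pos(pi=0.6), CD95=_pos()),
            planted_ab),
    ]
    return StudyDesign(
        conditions=conds,
        populations=pops,
        panel=panel,
        subjects_per_condition=subjects_per_condition,
        events_per_sample=events_per_sample,
        planted_dacs=(
            PlantedDAC("cd4_effmem_cd32_act", ("primary_HIV", "healthy"), 4.0),
            PlantedDAC("cd4_effmem_cd32_act", ("primary_HIV", "HIV_cART"), 2.0),
            PlantedDAC("cd4_effmem_cd32_act", ("HIV_cART", "healthy"), 2.0),
        ),
        planted_cc=PlantedCC("cd4_effmem_cd32_act", target_r=0.9),
        seed=seed,
    )


def tiny_design(seed: int = 0) -> StudyDesign:
    """Small design for fast end-to-end runs: 3 conditions x 3 subjects x
    800 events over a 10-marker panel."""
    conds = ("primary_HIV", "HIV_cART", "healthy")
    panel = make_panel(["CD32a", "CCR7", "CD45RA", "CD57", "CD27"], excluded=())
    planted_ab = {"primary_HIV": 0.06, "HIV_cART": 0.03, "healthy": 0.015}
    filler_ab = {c: 1.0 - 0.62 - planted_ab[c] for c in conds}
    pops = [
        PopulationSpec("b_cells", _lineage("CD45", "CD19"), _const(0.10, conds)),
        PopulationSpec("cd8_t", _lineage("CD45", "CD3", "CD8"), _const(0.20, conds)),
        PopulationSpec("cd4_naive", _cd4_base(CCR7=_pos(), CD45RA=_pos(), CD27=_pos()),
                       filler_ab),
        PopulationSpec("cd4_cm", _cd4_base(CCR7=_pos(), CD27=_pos()), _const(0.20, conds)),
        PopulationSpec("cd4_effmem", _cd4_base(CD57=_pos(pi=0.3)), _const(0.12, conds)),
        PopulationSpec("cd4_effmem_cd32", _cd4_base(CD32a=_pos(4.2), CD57=_pos()),
                       planted_ab),
    ]
    return StudyDesign(
        conditions=conds,
        populations=pops,
        panel=panel,
        subjects_per_condition=3,
        events_per_sample=800,
        planted_dacs=(PlantedDAC("cd4_effmem_cd32", ("primary_HIV", "healthy"), 4.0),),
        planted_cc=PlantedCC("cd4_effmem_cd32", target_r=0.9),
        seed=seed,
    )


def null_design(seed: int = 0, events_per_sample: int = 800) -> StudyDesign:
    """No planted effects: every population equally abundant in every
    condition; covariate independent of all abundances."""
    conds = ("primary_HIV", "HIV_cART", "healthy")
    panel = make_panel(["CD32a", "CCR7", "CD45RA", "CD57", "CD27"], excluded=())
    pops = [
        PopulationSpec("b_cells", _lineage("CD45", "CD19"), _const(0.10, conds)),
        PopulationSpec("cd8_t", _lineage("CD45", "CD3", "CD8"), _const(0.20, conds)),
        PopulationSpec("cd4_naive", _cd4_base(CCR7=_pos(), CD45RA=_pos()), _const(0.25, conds)),
        PopulationSpec("cd4_cm", _cd4_base(CCR7=_pos()), _const(0.20, conds)),
        PopulationSpec("cd4_effmem", _cd4_base(CD57=_pos(pi=0.3)), _const(0.15, conds)),
        PopulationSpec("cd4_cm_cd32", _cd4_base(CD32a=_pos(4.2), CCR7=_pos()),
                       _const(0.10, conds)),
    ]
    return StudyDesign(
        conditions=conds, populations=pops, panel=panel,
        subjects_per_condition=6, events_per_sample=events_per_sample, seed=seed,
    )
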