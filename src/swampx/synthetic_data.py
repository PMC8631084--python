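"""Forward-in-time allele-frequency simulator with sex-specific migration.

The simulator propagates population allele frequencies (not individuals)
under the Wright–Fisher model: each generation, each population's frequency
is binomially resampled with a class-specific copy number — 2N on autosomes,
⌊3N/2⌋ on the X, ⌊N/2⌋ for mitochondria (diploid size N, 1:1 sex ratio).
Sex-specific migration and admixture pulses act on frequencies through
class-specific effective rates: with female rate m_f and male rate m_m, the
fraction of allele copies replaced per generation is

    m_autosome = (m_f + m_m) / 2
    m_X        = (2 m_f + m_m) / 3
    m_mito     = m_f

because a female carries two X copies and a male one, and mitochondria are
maternally inherited.  Under purely male-mediated gene flow (m_f = 0) the X
therefore feels 2/3 of the autosomal migration pressure and the
mitochondrial genome none at all — the mechanism behind nuclear swamping,
where sustained male-biased introgression replaces a population's autosomes
while its mitochondrial (and, partially, X-linked) ancestry persists.

Loci are unlinked; linkage disequilibrium is absent by construction, which
makes block-jackknife standard errors exact-to-conservative on these data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genotype_data import (
    GenotypeMatrix,
    write_vcf,  # noqa: F401  (re-exported: the simulator's natural output path)
)

CLASS_ORDER = ("autosome", "X", "mito")


class DemographyError(ValueError):
    """Raised for inconsistent demographic models."""


class EffectiveRates(NamedTuple):
    autosome: float
    x: float
    mito: float


def effective_rates(m_f: float, m_m: float) -> EffectiveRates:
    """Per-class effective migration rates from sex-specific rates."""
    if not (0 <= m_f <= 1 and 0 <= m_m <= 1):
        raise DemographyError("migration rates must lie in [0, 1]")
    return EffectiveRates((m_f + m_m) / 2, (2 * m_f + m_m) / 3, m_f)


# ---------------------------------------------------------------------------
# demographic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    time: int
    parent: str
    children: tuple[str, str]


@dataclass(frozen=True)
class Pulse:
    """One-generation admixture: a fraction of the recipient is replaced."""

    time: int
    donor: str
    recipient: str
    alpha_f: float
    alpha_m: float


@dataclass(frozen=True)
class ContinuousMigration:
    """Per-generation replacement over [start, end) generations."""

    donor: str
    recipient: str
    m_f: float
    m_m: float
    start: int
    end: int


@dataclass
class DemographicModel:
    """Time-ordered splits, pulses, and continuous sex-specific migration.

    Times are forward generations from 0 (the root population's creation) to
    ``end_time`` (sampling).  ``populations`` maps every population that ever
    exists to its diploid size N; ``sample_plan`` maps sampled populations to
    (n_females, n_males).
    """

    populations: dict[str, int]
    root: str
    events: list = field(default_factory=list)
    end_time: int = 100
    sample_plan: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.root not in self.populations:
            raise DemographyError("root population missing from populations")
        for pop, n in self.populations.items():
            if n < 2:
                raise DemographyError(f"population {pop} needs N >= 2")
        creation = {self.root: 0}
        removal: dict[str, int] = {}
        def start_time(e):
            return e.start if isinstance(e, ContinuousMigration) else e.time

        for ev in sorted(self.events, key=start_time):
            if not (0 <= start_time(ev) <= self.end_time):
                raise DemographyError(
                    f"event time {start_time(ev)} outside history")
            if isinstance(ev, Split):
                if ev.parent not in creation or ev.parent in removal:
                    raise DemographyError(
                        f"split at {ev.time}: parent {ev.parent} not alive")
                for child in ev.children:
                    if child in creation:
                        raise DemographyError(f"population {child} created twice")
                    if child not in self.populations:
                        raise DemographyError(f"unknown population {child}")
                    creation[child] = ev.time
                removal[ev.parent] = ev.time
            elif isinstance(ev, Pulse):
                if not (0 <= ev.alpha_f <= 1 and 0 <= ev.alpha_m <= 1):
                    raise DemographyError("pulse fractions must lie in [0, 1]")
                self._check_alive(ev.donor, ev.time, creation, removal)
                self._check_alive(ev.recipient, ev.time, creation, removal)
            elif isinstance(ev, ContinuousMigration):
                effective_rates(ev.m_f, ev.m_m)  # range check
                if ev.start >= ev.end:
                    raise DemographyError("migration needs start < end")
                for t in (ev.start, ev.end - 1):
                    self._check_alive(ev.donor, t, creation, removal)
                    self._check_alive(ev.recipient, t, creation, removal)
            else:
                raise DemographyError(f"unknown event type {type(ev).__name__}")
        for pop in self.sample_plan:
            if pop in removal or pop not in creation:
                raise DemographyError(f"sampled population {pop} not alive at end")

    @staticmethod
    def _check_alive(pop, time, creation, removal) -> None:
        if pop not in creation or creation[pop] > time or \
                (pop in removal and removal[pop] <= time):
            raise DemographyError(f"population {pop} not alive at time {time}")

    def copies(self, pop: str, chrom_class: str) -> int:
        n = self.populations[pop]
        if chrom_class == "autosome":
            return 2 * n
        if chrom_class == "X":
            return (3 * n) // 2
        return n // 2  # mito: one maternally inherited copy per female


# ---------------------------------------------------------------------------
# locus plan
# ---------------------------------------------------------------------------

@dataclass
class LocusPlan:
    """How many unlinked loci to simulate and where to place them.

    Positions are laid out on ``n_autosome_chroms`` autosomes and one X at
    ``spacing`` bp apart, so a 5-Mb jackknife partition of the default plan
    (10^4 autosomal loci on 20 chromosomes at 25 kb) yields 60 autosomal
    blocks and 10 X blocks.  The ancestral-frequency sampler 'beta' draws
    Beta(0.8, 0.8) truncated to [0.05, 0.95] — a polymorphism-rich panel that
    resembles a complete-case SNV set; 'uniform' draws U(0.05, 0.95).
    """

    n_autosomal: int = 10_000
    n_x: int = 2_000
    n_mito: int = 1
    n_autosome_chroms: int = 20
    spacing: int = 25_000
    freq_sampler: str = "beta"

    def site_table(self) -> pd.DataFrame:
        rows = []
        per = np.full(self.n_autosome_chroms, self.n_autosomal // self.n_autosome_chroms)
        per[: self.n_autosomal % self.n_autosome_chroms] += 1
        for k, n in enumerate(per):
            for i in range(n):
                rows.append((f"chr{k + 1}", self.spacing * i + 1, "autosome"))
        for i in range(self.n_x):
            rows.append(("chrX", self.spacing * i + 1, "X"))
        for i in range(self.n_mito):
            rows.append(("chrM", i + 1, "mito"))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "chrom_class"])
        df["ref"] = "A"
        df["alt"] = "G"
        return df[["chrom", "pos", "ref", "alt", "chrom_class"]]

    def class_map(self) -> dict[str, str]:
        cmap = {f"chr{k + 1}": "autosome" for k in range(self.n_autosome_chroms)}
        cmap["chrX"] = "X"
        cmap["chrM"] = "mito"
        return cmap

    def n_loci(self, chrom_class: str) -> int:
        return {"autosome": self.n_autosomal, "X": self.n_x,
                "mito": self.n_mito}[chrom_class]

    def draw_ancestral(self, chrom_class: str,
                       rng: np.random.Generator) -> np.ndarray:
        n = self.n_loci(chrom_class)
        if self.freq_sampler == "uniform":
            return rng.uniform(0.05, 0.95, size=n)
        if self.freq_sampler != "beta":
            raise DemographyError(f"unknown freq sampler {self.freq_sampler!r}")
        p = rng.beta(0.8, 0.8, size=n)
        while True:  # truncate by redraw; acceptance ~ 0.7 so this terminates fast
            bad = (p < 0.05) | (p > 0.95)
            if not bad.any():
                return p
            p[bad] = rng.beta(0.8, 0.8, size=int(bad.sum()))


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth retained from a simulation run.

    ``ancestry`` tracks, per population and chromosome class, the expected
    fraction of ancestry attributable to each source population; a
    population's ancestry is reset to itself at its creation, and migration
    mixes the donor's vector in at the class-specific effective rate.  Drift
    does not enter this bookkeeping: it is the deterministic expectation of
    the admixture process, which for a constant class rate w gives donor
    fraction 1 − (1−w)^t after t generations.
    """

    seed: int
    ancestral_freqs: dict[str, np.ndarray]
    final_freqs: dict[str, dict[str, np.ndarray]]
    ancestry: dict[str, dict[str, dict[str, float]]]
    migration_trajectories: dict[tuple[str, str], dict[str, list[float]]]
    effective: dict[tuple[str, str], EffectiveRates]

    def donor_fraction(self, pop: str, donor: str, chrom_class: str) -> float:
        return self.ancestry[pop][chrom_class].get(donor, 0.0)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _mix(anc_rec: dict, anc_don: dict, w: float) -> dict:
    out = {k: (1 - w) * v for k, v in anc_rec.items()}
    for k, v in anc_don.items():
        out[k] = out.get(k, 0.0) + w * v
    return out


def simulate(model: DemographicModel, plan: LocusPlan,
             seed: int) -> tuple[GenotypeMatrix, TruthRecord]:
    """Run the forward simulation and sample genotypes.

    Bit-reproducible for a given seed: populations are always iterated in
    sorted order and classes in (autosome, X, mito) order.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    classes = [c for c in CLASS_ORDER if plan.n_loci(c) > 0]

    p0 = {c: plan.draw_ancestral(c, rng) for c in classes}
    freqs: dict[str, dict[str, np.ndarray]] = {
        model.root: {c: p0[c].copy() for c in classes}}
    ancestry: dict[str, dict[str, dict[str, float]]] = {
        model.root: {c: {model.root: 1.0} for c in classes}}

    splits = sorted((e for e in model.events if isinstance(e, Split)),
                    key=lambda e: e.time)
    pulses = sorted((e for e in model.events if isinstance(e, Pulse)),
                    key=lambda e: e.time)
    migrations = [e for e in model.events if isinstance(e, ContinuousMigration)]
    trajectories: dict[tuple[str, str], dict[str, list[float]]] = {
        (m.donor, m.recipient): {c: [] for c in classes} for m in migrations}
    eff = {(m.donor, m.recipient): effective_rates(m.m_f, m.m_m)
           for m in migrations}

    class_rate = {c: i for i, c in enumerate(("autosome", "x", "mito"))}

    for t in range(model.end_time):
        for ev in [e for e in splits if e.time == t]:
            for child in ev.children:
                freqs[child] = {c: freqs[ev.parent][c].copy() for c in classes}
                ancestry[child] = {c: {child: 1.0} for c in classes}
            del freqs[ev.parent], ancestry[ev.parent]
        for ev in [e for e in pulses if e.time == t]:
            w = effective_rates(ev.alpha_f, ev.alpha_m)
            for c in classes:
                wc = w[class_rate[c if c != "X" else "x"]]
                freqs[ev.recipient][c] = ((1 - wc) * freqs[ev.recipient][c]
                                          + wc * freqs[ev.donor][c])
                ancestry[ev.recipient][c] = _mix(
                    ancestry[ev.recipient][c], ancestry[ev.donor][c], wc)
        for ev in migrations:
            if ev.start <= t < ev.end:
                w = eff[(ev.donor, ev.recipient)]
                for c in classes:
                    wc = w[class_rate[c if c != "X" else "x"]]
                    freqs[ev.recipient][c] = ((1 - wc) * freqs[ev.recipient][c]
                                              + wc * freqs[ev.donor][c])
                    ancestry[ev.recipient][c] = _mix(
                        ancestry[ev.recipient][c], ancestry[ev.donor][c], wc)
                    trajectories[(ev.donor, ev.recipient)][c].append(
                        ancestry[ev.recipient][c].get(ev.donor, 0.0))
        # Wright–Fisher resampling, class-specific copy numbers
        for pop in sorted(freqs):
            for c in classes:
                copies = model.copies(pop, c)
                freqs[pop][c] = rng.binomial(copies, freqs[pop][c]) / copies

    gm = _sample_genotypes(model, plan, freqs, rng)
    truth = TruthRecord(
        seed=seed,
        ancestral_freqs=p0,
        final_freqs={p: {c: f.copy() for c, f in fc.items()}
                     for p, fc in freqs.items()},
        ancestry=ancestry,
        migration_trajectories=trajectories,
        effective=eff,
    )
    return gm, truth


def _sample_genotypes(model: DemographicModel, plan: LocusPlan,
                      freqs: dict, rng: np.random.Generator) -> GenotypeMatrix:
    sites = plan.site_table()
    classes = [c for c in CLASS_ORDER if plan.n_loci(c) > 0]
    sample_rows, columns = [], []
    for pop in sorted(model.sample_plan):
        if pop not in freqs:
            raise DemographyError(f"sampled population {pop} not alive at end")
        n_f, n_m = model.sample_plan[pop]
        for i in range(n_f):
            sample_rows.append((f"{pop}_F{i + 1}", pop, "female"))
        for i in range(n_m):
            sample_rows.append((f"{pop}_M{i + 1}", pop, "male"))
        for sid, _, sex in sample_rows[len(columns):]:
            col = np.empty(len(sites), dtype=np.int16)
            offset = 0
            for c in classes:
                n = plan.n_loci(c)
                if c == "autosome":
                    ploidy = 2
                elif c == "X":
                    ploidy = 2 if sex == "female" else 1
                else:
                    ploidy = 1
                col[offset:offset + n] = rng.binomial(ploidy, freqs[pop][c])
                offset += n
            columns.append(col)
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "population", "sex"])
    dosage = (np.column_stack(columns) if columns
              else np.empty((len(sites), 0), dtype=np.int16))
    return GenotypeMatrix(sites, samples, dosage)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def nuclear_swamping_scenario(
    strength: float = 0.02,
    duration: int = 150,
    seed: int = 0,
    n_diploid: int = 500,
    plan: LocusPlan | None = None,
    include_donor: bool = True,
) -> tuple[DemographicModel, GenotypeMatrix, TruthRecord]:
    """The four-population nuclear-swamping layout.

    Outgroup A splits first; the ancestor of the sister pair (B, C) splits
    from the D lineage and passes through a founder bottleneck (N/5), giving
    B and C a strongly drifted shared "original" ancestry; the donor Dp is
    D's sister population and sends male-only migrants (m_f = 0,
    m_m = ``strength``) into C for ``duration`` generations.  Cumulative
    donor ancestry therefore grows fastest on the autosomes, at 2/3 the
    per-generation pressure on the X, and not at all on the mitochondrial
    genome — C keeps its original maternal lineage, the autosomes are
    largely replaced, and f4(A, B; C, D) sits further below zero on the X
    than on the autosomes.

    With ``include_donor`` the donor population is sampled too, which makes
    the admixture-graph fit well-determined; the autosome-vs-X f4 contrast
    uses only (A, B; C, D).
    """
    if not (0 < strength < 1):
        raise DemographyError("strength must lie in (0, 1)")
    if duration < 1:
        raise DemographyError("duration must be >= 1")
    plan = plan or LocusPlan()
    mig_start = 230
    end = mig_start + duration + 20  # post-contact drift tail
    pops = {p: n_diploid for p in
            ["A", "B", "C", "D", "Dp", "root", "anc1", "ancD"]}
    pops["ancBC"] = max(n_diploid // 5, 10)  # founder bottleneck
    sampled = ["A", "B", "C", "D"] + (["Dp"] if include_donor else [])
    model = DemographicModel(
        populations=pops,
        root="root",
        events=[
            Split(0, "root", ("A", "anc1")),
            Split(30, "anc1", ("ancBC", "ancD")),
            Split(60, "ancD", ("D", "Dp")),
            Split(210, "ancBC", ("B", "C")),
            ContinuousMigration("Dp", "C", m_f=0.0, m_m=strength,
                                start=mig_start, end=mig_start + duration),
        ],
        end_time=end,
        sample_plan={p: (2, 2) for p in sampled},
    )
    gm, truth = simulate(model, plan, seed)
    return model, gm, truth


def treeness_null_scenario(
    seed: int, n_diploid: int = 100, plan: LocusPlan | None = None
) -> tuple[DemographicModel, GenotypeMatrix, TruthRecord]:
    """Clean tree (O,(B,(C,D))): every f4(O,B;C,D) is zero in expectation."""
    plan = plan or LocusPlan(n_x=0, n_mito=0)
    model = DemographicModel(
        populations={p: n_diploid for p in
                     ["O", "B", "C", "D", "root", "anc1", "anc2"]},
        root="root",
        events=[
            Split(0, "root", ("O", "anc1")),
            Split(40, "anc1", ("B", "anc2")),
            Split(80, "anc2", ("C", "D")),
        ],
        end_time=130,
        sample_plan={p: (2, 2) for p in ["O", "B", "C", "D"]},
    )
    gm, truth = simulate(model, plan, seed)
    return model, gm, truth


def gene_flow_scenario(
    seed: int, target: str = "C", m: float = 0.01,
    n_diploid: int = 100, plan: LocusPlan | None = None
) -> tuple[DemographicModel, GenotypeMatrix, TruthRecord]:
    """Tree (O,(B,(C,D))) plus sex-balanced B → target continuous migration.

    Flow into C drives pooled f4(O,B;C,D) negative; flow into D drives it
    positive (the sign convention of the admixture test).
    """
    if target not in ("C", "D"):
        raise DemographyError("target must be 'C' or 'D'")
    plan = plan or LocusPlan(n_x=0, n_mito=0)
    model = DemographicModel(
        populations={p: n_diploid for p in
                     ["O", "B", "C", "D", "root", "anc1", "anc2"]},
        root="root",
        events=[
            Split(0, "root", ("O", "anc1")),
            Split(40, "anc1", ("B", "anc2")),
            Split(80, "anc2", ("C", "D")),
            ContinuousMigration("B", target, m_f=m, m_m=m, start=90, end=120),
        ],
        end_time=130,
        sample_plan={p: (2, 2) for p in ["O", "B", "C", "D"]},
    )
    gm, truth = simulate(model, plan, seed)
    return model, gm, truth


def pulse_admixture_scenario(
    seed: int, alpha: float = 0.3, n_diploid: int = 100,
    plan: LocusPlan | None = None
) -> tuple[DemographicModel, GenotypeMatrix, TruthRecord]:
    """Five sampled populations with one sex-balanced pulse Dp → C.

    Topology (O, ((B, C), (D, Dp))); at the pulse, a fraction ``alpha`` of C
    is replaced by the donor Dp.  This is the parameter-recovery scenario for
    admixture-graph fitting: C is an admixture node with weight 1 − alpha
    toward its tree-side parent.
    """
    plan = plan or LocusPlan(n_x=0, n_mito=0)
    model = DemographicModel(
        populations={p: n_diploid for p in
                     ["O", "B", "C", "D", "Dp", "root", "anc1", "ancBC", "ancD"]},
        root="root",
        events=[
            Split(0, "root", ("O", "anc1")),
            Split(40, "anc1", ("ancBC", "ancD")),
            Split(80, "ancBC", ("B", "C")),
            Split(80, "ancD", ("D", "Dp")),
            Pulse(110, "Dp", "C", alpha_f=alpha, alpha_m=alpha),
        ],
        end_time=140,
        sample_plan={p: (2, 2) for p in ["O", "B", "C", "D", "Dp"]},
    )
    gm, truth = simulate(model, plan, seed)
    return model, gm, truth


def counts_from_frequencies(freqs: np.ndarray, n_copies: int,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Binomial allele counts for a pseudo-population sampled at ``freqs``."""
    derived = rng.binomial(n_copies, freqs)
    return derived, np.full_like(derived, n_copies)


# ---------------------------------------------------------------------------
# graph skeletons matching the scenario presets
# ---------------------------------------------------------------------------

def scenario_graph_skeleton(kind: str = "swamping"):
    """Admixture-graph topology matching a scenario preset.

    ``swamping`` (leaves A, B, C, D, Dp) and ``pulse`` (leaves O, B, C, D,
    Dp) share the same shape: the admixed population C mixes a source on its
    own tree branch (weight α toward the original side) with a source on the
    donor Dp's branch.  Continuous migration is summarized by a single
    admixture event, the standard graph-level compression of sustained flow.
    Drift lengths are free parameters; only the topology matters here.
    """
    from .admixture_graph import AdmixtureGraph

    if kind == "swamping":
        out, others = "A", ("B", "C", "D")
    elif kind == "pulse":
        out, others = "O", ("B", "C", "D")
    else:
        raise DemographyError(f"unknown skeleton kind {kind!r}")
    b, c, d = others
    g = AdmixtureGraph()
    g.add_edge("R", out, 0.05)
    g.add_edge("R", "n1", 0.01)
    g.add_edge("n1", "n2", 0.02)
    g.add_edge("n1", "n3", 0.02)
    g.add_edge("n2", b, 0.02)
    g.add_edge("n2", "cmid", 0.01)
    g.add_edge("n3", d, 0.02)
    g.add_edge("n3", "mD", 0.01)
    g.add_edge("mD", "Dp", 0.02)
    g.add_admixture("mix", "cmid", "mD", alpha=0.5)
    g.add_edge("mix", c, 0.01)
    g.validate()
    return g
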