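"""Seeded generators for every input the pipeline consumes.

The generators reproduce the statistical structure the downstream
analyses assume: codon families whose duplications arrive in periodic
bursts and then diverge neutrally at a stated per-year rate; a
constant-rate Muse–Gaut-style codon-model null with dN/dS = 2.0 and
unequal base frequencies; Poisson mapped-read counts for multi-copy
families against single-copy controls; composite-likelihood-ratio tracks
with implanted sweep peaks; and a two-regime glacial oscillation curve
(~40-kyr cycles beyond 1 Mya, ~100-kyr cycles since).

Sequence evolution is a per-lineage Poisson jump process over codons:
proposals arrive per nucleotide site, synonymous changes are accepted at
relative rate 1, nonsynonymous at relative rate omega, and changes
creating stop codons are rejected (unless the copy is pseudogenized,
after which everything is accepted).  No indels are simulated, so a
family is aligned by construction.  With this parametrization the
synonymous substitution rate per synonymous site equals the per-site
proposal rate, so a copy pair of age t has expected dS = 2*mu*t.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import GlacialCurve, SequenceRecord
from .molevo import GENETIC_CODE, SENSE_CODONS, codon_site_counts, is_sense_codon

_BASES = "ACGT"

#: neutral per-site per-year rate used for the zona pellucida dating
DEFAULT_MU_YEAR = 4.0e-9
#: base frequencies (A, C, G, T) of the constant-rate null
NULL_PI = (0.2, 0.3, 0.4, 0.1)
#: dN/dS of the constant-rate null
NULL_OMEGA = 2.0


@dataclass(frozen=True)
class BurstSimConfig:
    """Configuration of the periodic-burst family simulator.

    burst_times are years before present, strictly decreasing toward the
    present (oldest first); at each burst, ``copies_per_burst``
    duplication events occur among the extant copies.  ``mu_year`` is the
    neutral per-site per-year substitution rate, ``omega`` the dN/dS
    ratio, ``pi`` the base frequencies used to draw the root sequence.
    ``pseudogenization_rate`` is a per-copy per-year hazard after which a
    copy accepts premature stops (0 disables degeneration).
    """

    seed: int
    n_codons: int = 650
    mu_year: float = DEFAULT_MU_YEAR
    omega: float = 0.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    burst_times: tuple[float, ...] = ()
    copies_per_burst: int = 8
    extra_root_copies: int = 0
    pseudogenization_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", tuple(float(p) for p in self.pi))
        object.__setattr__(self, "burst_times", tuple(float(t) for t in self.burst_times))
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if any(p < 0 for p in self.pi):
            raise ValueError("pi must be non-negative")
        if self.mu_year <= 0:
            raise ValueError("mu_year must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_codons < 50:
            raise ValueError("n_codons must be >= 50")
        if self.copies_per_burst < 1:
            raise ValueError("copies_per_burst must be >= 1")
        if self.extra_root_copies < 0 or self.pseudogenization_rate < 0:
            raise ValueError("negative count or rate")
        times = self.burst_times
        if any(t <= 0 for t in times):
            raise ValueError("burst times must be positive years BP")
        if any(t1 <= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("burst_times must be strictly decreasing toward present")


@dataclass(frozen=True)
class DuplicationHistory:
    """Ground-truth duplication events of a simulated family."""

    events: tuple[tuple[float, str, str], ...]  # (years BP, parent, child)
    tip_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        children = [c for _, _, c in self.events]
        if len(set(children)) != len(children):
            raise ValueError("a child copy may appear only once")

    @property
    def event_times(self) -> tuple[float, ...]:
        return tuple(t for t, _, _ in self.events)


def _random_root_codons(rng: np.random.Generator, n_codons: int,
                        pi: tuple[float, ...]) -> list[str]:
    """Draw sense codons with probability proportional to the product of
    base frequencies (the stationary distribution of the MG-style chain)."""
    pi_map = dict(zip(_BASES, pi))
    weights = np.array(
        [pi_map[c[0]] * pi_map[c[1]] * pi_map[c[2]] for c in SENSE_CODONS]
    )
    weights /= weights.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=weights)
    return [SENSE_CODONS[i] for i in idx]


def _evolve_lineage(
    codons: list[str],
    duration_years: float,
    mu_year: float,
    omega: float,
    rng: np.random.Generator,
    pseudogenized: bool = False,
    pi: tuple[float, float, float, float] | None = None,
) -> list[str]:
    """Evolve one copy in place-free fashion for ``duration_years``.

    Proposals arrive as a Poisson process at rate ``mu_year`` per
    nucleotide site (times max(1, omega) so acceptance thinning can model
    omega > 1).  Mutation targets are uniform among the 3 alternative
    bases, or drawn from ``pi`` when given (the MG-style null).
    Synonymous changes are accepted with relative rate 1, nonsynonymous
    with relative rate omega; stop-creating changes are rejected unless
    the copy is pseudogenized (then everything is accepted).
    """
    if duration_years <= 0:
        return list(codons)
    codons = list(codons)
    n_sites = 3 * len(codons)
    alpha = max(1.0, omega)
    n_prop = rng.poisson(mu_year * alpha * n_sites * duration_years)
    if n_prop == 0:
        return codons
    sites = rng.integers(0, n_sites, size=n_prop)
    accept_u = rng.random(n_prop)
    if pi is None:
        base_choice = rng.integers(0, 3, size=n_prop)
    else:
        base_choice = rng.choice(4, size=n_prop, p=np.asarray(pi))
    for k in range(n_prop):
        site = int(sites[k])
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        cur = codon[pos]
        if pi is None:
            alts = [b for b in _BASES if b != cur]
            new_base = alts[int(base_choice[k])]
        else:
            new_base = _BASES[int(base_choice[k])]
            if new_base == cur:
                continue
        new_codon = codon[:pos] + new_base + codon[pos + 1:]
        old_aa = GENETIC_CODE.get(codon, "*")
        new_aa = GENETIC_CODE[new_codon]
        if pseudogenized:
            codons[ci] = new_codon
            continue
        if new_aa == "*":
            continue
        if new_aa == old_aa:
            accept_p = 1.0 / alpha
        else:
            accept_p = omega / alpha
        if accept_u[k] < accept_p:
            codons[ci] = new_codon
    return codons


@dataclass
class _Copy:
    name: str
    codons: list[str]
    pseudo_since: float | None = None  # years BP at which it pseudogenized


def simulate_burst_family(
    config: BurstSimConfig,
) -> tuple[list[SequenceRecord], DuplicationHistory]:
    """Simulate a codon family expanding in periodic duplication bursts.

    The family starts from one random root copy (plus
    ``extra_root_copies`` identical duplicates) at the oldest burst time;
    at each burst, ``copies_per_burst`` duplication events pick parents at
    random among the extant copies (without replacement while the pool
    lasts).  Between events every lineage evolves independently under the
    Poisson substitution process.  Returns the aligned tip sequences and
    the true duplication history.
    """
    rng = np.random.default_rng(config.seed)
    root = _random_root_codons(rng, config.n_codons, config.pi)
    if not config.burst_times:
        rec = SequenceRecord("copy_0", "".join(root))
        return [rec], DuplicationHistory(events=(), tip_ids=("copy_0",))
    t_start = config.burst_times[0]
    pool: list[_Copy] = [_Copy("copy_0", list(root))]
    for i in range(config.extra_root_copies):
        pool.append(_Copy(f"copy_{i + 1}", list(root)))
    next_id = len(pool)
    events: list[tuple[float, str, str]] = []
    now = t_start
    for t_burst in config.burst_times:
        # evolve everyone down to the burst time
        dt = now - t_burst
        if dt > 0:
            pool = _advance(pool, now, t_burst, config, rng)
        now = t_burst
        # duplication events: parents without replacement while possible
        order = list(rng.permutation(len(pool)))
        for e in range(config.copies_per_burst):
            if not order:
                order = list(rng.permutation(len(pool)))
            parent = pool[int(order.pop(0))]
            child = _Copy(f"copy_{next_id}", list(parent.codons),
                          pseudo_since=parent.pseudo_since)
            next_id += 1
            pool.append(child)
            events.append((t_burst, parent.name, child.name))
    pool = _advance(pool, now, 0.0, config, rng)
    records = [SequenceRecord(c.name, "".join(c.codons)) for c in pool]
    history = DuplicationHistory(events=tuple(events),
                                 tip_ids=tuple(c.name for c in pool))
    return records, history


def _advance(pool: list[_Copy], t_from: float, t_to: float,
             config: BurstSimConfig, rng: np.random.Generator) -> list[_Copy]:
    """Evolve every copy from t_from down to t_to (years BP), drawing
    pseudogenization times from the per-year hazard."""
    dt = t_from - t_to
    out: list[_Copy] = []
    for copy in pool:
        pseudo_since = copy.pseudo_since
        if pseudo_since is None and config.pseudogenization_rate > 0:
            wait = rng.exponential(1.0 / config.pseudogenization_rate)
            if wait < dt:
                pseudo_since = t_from - wait
        if pseudo_since is None or pseudo_since <= t_to:
            codons = _evolve_lineage(copy.codons, dt, config.mu_year,
                                     config.omega, rng)
        else:
            functional_span = max(t_from - min(t_from, pseudo_since), 0.0)
            broken_span = dt - functional_span
            codons = _evolve_lineage(copy.codons, functional_span,
                                     config.mu_year, config.omega, rng)
            codons = _evolve_lineage(codons, broken_span, config.mu_year,
                                     config.omega, rng, pseudogenized=True)
        out.append(_Copy(copy.name, codons, pseudo_since))
    return out


def simulate_null_family(
    seed: int,
    n_tips: int,
    n_codons: int,
    tree_depth: float,
    omega: float = NULL_OMEGA,
    pi: tuple[float, float, float, float] = NULL_PI,
) -> list[SequenceRecord]:
    """Constant-rate codon-model null: no periodic burst structure.

    Sequences evolve on a random Yule (pure-birth) tree rescaled to
    root-to-tip depth ``tree_depth`` (expected neutral substitutions per
    site), under a Muse–Gaut-style codon model: mutation targets drawn
    from ``pi`` (the same frequencies at all three codon positions),
    nonsynonymous changes accepted at relative rate ``omega`` = 2.0 by
    default, stop codons rejected.
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    if n_codons < 1 or tree_depth <= 0:
        raise ValueError("n_codons and tree_depth must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(int(rng.integers(0, 2**31 - 1))),
    )
    tree.calc_node_ages(ultrametricity_precision=False)
    depth = tree.seed_node.age
    scale = tree_depth / depth if depth > 0 else 0.0
    root_codons = _random_root_codons(rng, n_codons, pi)
    records: list[SequenceRecord] = []
    tip_counter = [0]

    def recurse(node, codons: list[str]) -> None:
        blen = (node.edge.length or 0.0) * scale
        # evolve with mu_year=1 over "years" = branch length in subs/site
        codons = _evolve_lineage(codons, blen, 1.0, omega, rng, pi=pi)
        if node.is_leaf():
            tip_counter[0] += 1
            records.append(SequenceRecord(f"tip_{tip_counter[0]}", "".join(codons)))
        else:
            for child in node.child_nodes():
                recurse(child, codons)

    for child in tree.seed_node.child_nodes():
        recurse(child, root_codons)
    if tree.seed_node.is_leaf():  # degenerate, cannot happen for n_tips >= 4
        records.append(SequenceRecord("tip_1", "".join(root_codons)))
    return records


@dataclass(frozen=True)
class CnvDesign:
    """True copy numbers per population for target families and controls.

    ``samples`` maps sample_id -> population; ``true_cn`` maps
    (population, gene_id) -> copy number; ``gene_lengths`` in bp;
    ``library_sizes`` in total mapped reads per sample.  ``depth_scale``
    converts copy*bp*library into expected mapped reads (default tuned to
    ~50x coverage at library size 1e6 and CN 1).
    """

    samples: dict[str, str]
    true_cn: dict[tuple[str, str], float]
    gene_lengths: dict[str, int]
    library_sizes: dict[str, float]
    depth_scale: float = 5e-8

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.true_cn.values()):
            raise ValueError("copy numbers must be >= 0")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be > 0")
        if any(v <= 0 for v in self.gene_lengths.values()):
            raise ValueError("gene lengths must be > 0")


def simulate_cnv_counts(seed: int, design: CnvDesign):
    """Poisson mapped-read counts: mean = CN * gene_length * library * scale."""
    from .cnv import ReadCountTable  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows = []
    for sample, pop in design.samples.items():
        lib = design.library_sizes[sample]
        for gene, length in design.gene_lengths.items():
            cn = design.true_cn.get((pop, gene), 1.0)
            mean = cn * length * lib * design.depth_scale
            rows.append((sample, pop, gene, int(rng.poisson(mean))))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["sample", "population", "gene", "mapped_reads"])
    return ReadCountTable(df, dict(design.gene_lengths), dict(design.library_sizes))


def simulate_clr_track(
    seed: int,
    n_positions: int,
    sweep_centers: tuple[int, ...] = (),
    sweep_height: float = 50.0,
    sweep_halfwidth: int = 500,
    background_scale: float = 1.0,
    chrom: str = "chr1",
    step: int = 1,
):
    """CLR track with exponential background and triangular sweep bumps."""
    from .sweeps import CLRTrack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    positions = np.arange(1, n_positions * step + 1, step, dtype=int)
    clr = rng.exponential(background_scale, size=positions.size)
    for center in sweep_centers:
        bump = sweep_height * np.clip(1.0 - np.abs(positions - center) / sweep_halfwidth, 0.0, None)
        clr = clr + bump
    return CLRTrack(chrom=chrom, positions=positions, clr=clr)


def synthetic_glacial_curve(
    t_max: float = 1.8e6,
    switch: float = 1.0e6,
    period_old: float = 4.0e4,
    period_recent: float = 1.0e5,
    step: float = 1e3,
    mean_d18o: float = 4.0,
    amplitude: float = 0.5,
) -> GlacialCurve:
    """Two-regime sinusoidal glacial oscillation, continuous at the switch.

    Emulates the Quaternary d18O stack: ~100-kyr cycles in the recent
    1 Myr, ~40-kyr cycles beyond, with high d18O = glacial maxima.
    """
    ages = np.arange(0.0, t_max + 0.5 * step, step)
    phase = np.where(
        ages <= switch,
        2.0 * np.pi * ages / period_recent,
        2.0 * np.pi * (switch / period_recent + (ages - switch) / period_old),
    )
    d18o = mean_d18o + amplitude * np.cos(phase)
    return GlacialCurve(age=ages, d18o=d18o)
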