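"""Structured-coalescent simulation engine.

Backward-in-time coalescent with named demes, piecewise-constant sizes,
population splits, and migration, in the continuous-time approximation.
Time is measured in generations, increasing into the past.

Conventions (stated explicitly because they differ between tools):

* The deme size parameter ``N`` is the *diploid* effective size by
  default: the pairwise coalescence rate is 1/(2N) per generation
  (``ploidy=2``).  Haploid, maternally inherited loci (the plastome) use
  ``ploidy=1`` so that a deme of size ``N`` holds N haploid copies and
  pairs coalesce at rate 1/N.
* Migration rates are forward-in-time fractions: ``rate`` with donor d
  and recipient r means a fraction m of deme r is replaced by migrants
  from d each generation.  Backward in time this is implemented as each
  lineage currently in r jumping to d at rate m per generation.
* A split event merges its derived demes into the ancestral deme,
  backward in time, at the stated time.

Genealogies are returned as flat branch lists: each non-root lineage
contributes (branch length, leaf bitmask).  This supports both the
branch-statistic estimator of the expected SFS (no mutations needed)
and mutation dropping for sequences and SNP matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, HaplotypeAlignment, MISSING


@dataclass
class SizeChange:
    time: float
    deme: str
    size: float


@dataclass
class Split:
    time: float
    derived: list[str]
    ancestral: str


@dataclass
class Admixture:
    """Hybrid origin: backward in time, at ``time`` every lineage in
    ``deme`` jumps independently to one of ``parents`` with the given
    proportions; the deme is then empty."""

    time: float
    deme: str
    parents: list[str]
    proportions: list[float]


@dataclass
class Migration:
    donor: str
    recipient: str
    rate: float
    start_time: float = 0.0
    end_time: float = math.inf


@dataclass
class DemographicModel:
    """Named demes with piecewise-constant sizes, splits and migration."""

    deme_sizes: dict[str, float]
    size_changes: list[SizeChange] = field(default_factory=list)
    splits: list[Split] = field(default_factory=list)
    migrations: list[Migration] = field(default_factory=list)
    admixtures: list[Admixture] = field(default_factory=list)
    ploidy: int = 2
    mutation_rate: float = 0.0  # per site per generation
    locus_length: int = 1

    def __post_init__(self) -> None:
        for name, size in self.deme_sizes.items():
            if size <= 0:
                raise ValueError(f"deme {name!r} has non-positive size")
        for ev in self.size_changes:
            if ev.time <= 0 or ev.size <= 0:
                raise ValueError("size changes need positive time and size")
        for sp in self.splits:
            if sp.time <= 0:
                raise ValueError("split times must be positive")
        for mg in self.migrations:
            if not 0 <= mg.rate < 1:
                raise ValueError("migration rates must lie in [0, 1)")
        for ad in self.admixtures:
            if ad.time <= 0 or abs(sum(ad.proportions) - 1.0) > 1e-9:
                raise ValueError("admixture needs positive time and proportions summing to 1")
        self.admixtures = sorted(self.admixtures, key=lambda e: e.time)
        self.size_changes = sorted(self.size_changes, key=lambda e: e.time)
        self.splits = sorted(self.splits, key=lambda e: e.time)
        for sp in self.splits:
            has_size = sp.ancestral in self.deme_sizes or any(
                ev.deme == sp.ancestral and ev.time <= sp.time
                for ev in self.size_changes
            )
            if not has_size:
                raise ValueError(
                    f"ancestral deme {sp.ancestral!r} has no size (add it to "
                    "deme_sizes or give a size change at or before the split)"
                )
        # after all splits every deme must trace to a single ancestor
        if len(self.deme_sizes) > 1:
            parent = {d: d for d in self._all_demes()}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for sp in self.splits:
                for d in sp.derived:
                    parent[find(d)] = find(sp.ancestral)
            for ad in self.admixtures:
                for p in ad.parents:
                    parent[find(ad.deme)] = find(p)
            roots = {find(d) for d in self.deme_sizes}
            if len(roots) > 1 and not self.migrations:
                raise ValueError(
                    "multiple demes never merge and no migration is defined"
                )
            self._n_components = len(roots)
        else:
            self._n_components = 1

    def _all_demes(self) -> set[str]:
        demes = set(self.deme_sizes)
        for sp in self.splits:
            demes |= set(sp.derived) | {sp.ancestral}
        for ev in self.size_changes:
            demes.add(ev.deme)
        for ad in self.admixtures:
            demes |= {ad.deme} | set(ad.parents)
        return demes

    def single_deme_epochs(self) -> list[tuple[float, float]] | None:
        """(start_time, size) epochs if the model is one unstructured deme."""
        if len(self.deme_sizes) != 1 or self.splits or self.migrations or self.admixtures:
            return None
        (deme, n0), = self.deme_sizes.items()
        epochs = [(0.0, n0)]
        for ev in self.size_changes:
            if ev.deme != deme:
                return None
            epochs.append((ev.time, ev.size))
        return epochs


@dataclass
class Genealogy:
    """One simulated tree as flat branch segments."""

    branches: list[tuple[float, int, float]]  # (length, leaf bitmask, end time)
    n_leaves: int
    leaf_demes: list[str]
    tmrca: float

    @property
    def total_length(self) -> float:
        return sum(b for b, _, _ in self.branches)

    def class_lengths(self) -> np.ndarray:
        """Total branch length subtending exactly j leaves, j = 0..n."""
        out = np.zeros(self.n_leaves + 1)
        for blen, mask, _ in self.branches:
            out[mask.bit_count()] += blen
        return out


def _check_connectivity(model: DemographicModel, sampled: list[str]) -> None:
    """Error out when sampled demes can never share a common ancestor."""
    parent = {d: d for d in model._all_demes()}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sp in model.splits:
        for d in sp.derived:
            parent[find(d)] = find(sp.ancestral)
    for ad in model.admixtures:
        for p in ad.parents:
            parent[find(ad.deme)] = find(p)
    for mg in model.migrations:
        if mg.rate > 0:
            parent[find(mg.donor)] = find(mg.recipient)
    roots = {find(d) for d in sampled}
    if len(roots) > 1:
        raise ValueError(
            "lineages stranded: sampled demes are disconnected "
            "(no migration and no shared ancestor)"
        )


def simulate_genealogy(
    model: DemographicModel,
    sample_config: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one structured-coalescent genealogy.

    ``sample_config`` assigns haploid sample counts to present-day demes.
    Within a deme, k lineages coalesce at total rate k(k-1)/2 / (ploidy*N)
    per generation; migration moves single lineages between demes; size
    changes and splits are instantaneous at their event times.
    """
    sampled = [d for d, k in sample_config.items() if k > 0]
    for d in sampled:
        if d not in model.deme_sizes:
            raise ValueError(f"sampled deme {d!r} not in model")
    _check_connectivity(model, sampled)

    sizes = dict(model.deme_sizes)
    # a deme is extinct once merged away (split) or dissolved (admixture);
    # migration involving an extinct endpoint must stop, otherwise lineages
    # could be marooned in a deme that no longer joins the tree
    extinct: dict[str, float] = {}
    for sp in model.splits:
        for d in sp.derived:
            if d != sp.ancestral:
                extinct[d] = min(extinct.get(d, math.inf), sp.time)
    for ad in model.admixtures:
        extinct[ad.deme] = min(extinct.get(ad.deme, math.inf), ad.time)
    # timeline of demographic events
    events: list[tuple[float, str, object]] = (
        [(ev.time, "size", ev) for ev in model.size_changes]
        + [(ad.time, "admix", ad) for ad in model.admixtures]
        + [(sp.time, "split", sp) for sp in model.splits]
    )
    events.sort(key=lambda e: e[0])

    # lineages[deme] -> list of [mask, birth_time]
    lineages: dict[str, list[list]] = {}
    leaf_demes: list[str] = []
    idx = 0
    for d in sampled:
        lineages[d] = []
        for _ in range(sample_config[d]):
            lineages[d].append([1 << idx, 0.0])
            leaf_demes.append(d)
            idx += 1
    n_leaves = idx
    branches: list[tuple[float, int, float]] = []
    t = 0.0
    ev_i = 0
    ploidy = model.ploidy

    def n_lineages() -> int:
        return sum(len(v) for v in lineages.values())

    while n_lineages() > 1:
        # rates under current state
        coal = []
        for d, lins in lineages.items():
            k = len(lins)
            if k >= 2:
                coal.append((d, k * (k - 1) / 2.0 / (ploidy * sizes[d])))
        mig = []
        for mg in model.migrations:
            if (
                mg.rate > 0
                and mg.start_time <= t < mg.end_time
                and t < extinct.get(mg.donor, math.inf)
                and t < extinct.get(mg.recipient, math.inf)
            ):
                k = len(lineages.get(mg.recipient, ()))
                if k:
                    mig.append((mg, mg.rate * k))
        total = sum(r for _, r in coal) + sum(r for _, r in mig)
        t_next_event = events[ev_i][0] if ev_i < len(events) else math.inf
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if t + wait >= t_next_event:
            if math.isinf(t_next_event):
                raise RuntimeError("no event possible: lineages stranded")
            t = t_next_event
            _, kind, ev = events[ev_i]
            ev_i += 1
            if kind == "size":
                sizes[ev.deme] = ev.size
            elif kind == "admix":
                movers = lineages.pop(ev.deme, [])
                props = np.asarray(ev.proportions)
                for lin in movers:
                    dest = ev.parents[int(rng.choice(len(props), p=props))]
                    lineages.setdefault(dest, []).append(lin)
            else:  # split: merge derived demes into ancestral
                dest = lineages.setdefault(ev.ancestral, [])
                for d in ev.derived:
                    if d == ev.ancestral:
                        continue
                    dest.extend(lineages.pop(d, []))
            continue
        t += wait
        u = rng.uniform(0.0, total)
        chosen = None
        for d, r in coal:
            if u < r:
                chosen = ("coal", d)
                break
            u -= r
        if chosen is None:
            for mg, r in mig:
                if u < r:
                    chosen = ("mig", mg)
                    break
                u -= r
        if chosen is None:  # numerical edge: take the last rate
            chosen = ("coal", coal[-1][0]) if coal else ("mig", mig[-1][0])
        if chosen[0] == "coal":
            lins = lineages[chosen[1]]
            k = len(lins)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if j < i:
                i, j = j, i
            a = lins[i]
            b = lins.pop(j)
            branches.append((t - a[1], a[0], t))
            branches.append((t - b[1], b[0], t))
            lins[i] = [a[0] | b[0], t]
        else:
            mg = chosen[1]
            lins = lineages[mg.recipient]
            i = int(rng.integers(len(lins)))
            lin = lins.pop(i)
            lineages.setdefault(mg.donor, []).append(lin)
            sizes.setdefault(mg.donor, model.deme_sizes.get(mg.donor, 1.0))

    return Genealogy(
        branches=branches, n_leaves=n_leaves, leaf_demes=leaf_demes, tmrca=t
    )


# ---------------------------------------------------------------------------
# expected SFS (branch-statistic estimator)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _njit(f):
        return f


@_njit
def _accumulate_class_lengths(exps, idx_i, idx_j, starts, pops, ends, n, ploidy):
    """Inner loop of the single-deme branch-statistic estimator.

    ``exps`` holds the unit-exponential waiting draws and ``idx_i``/
    ``idx_j`` the pair-merge choices, both pre-drawn so that the random
    stream is defined by the caller, not by the compiled code.
    """
    R = exps.shape[1]
    n_epochs = len(starts)
    xi = np.zeros(n + 1)
    t = np.zeros(R)
    sizes = np.ones((R, n), dtype=np.int64)
    for step in range(n - 1):
        k = n - step
        for r in range(R):
            rem = exps[step, r]
            cur = t[r]
            T = cur
            for e in range(n_epochs):
                lam = k * (k - 1) / 2.0 / (ploidy * pops[e])
                lo = cur if cur > starts[e] else starts[e]
                span = ends[e] - lo
                if span < 0.0:
                    span = 0.0
                cap = lam * span
                if rem <= cap:
                    T = lo + rem / lam
                    break
                rem -= cap
            wait = T - t[r]
            for c in range(k):
                xi[sizes[r, c]] += wait
            i = idx_i[step, r]
            j = idx_j[step, r]
            if j >= i:
                j += 1
            sizes[r, i] = sizes[r, i] + sizes[r, j]
            sizes[r, j] = sizes[r, k - 1]
            t[r] = T
    return xi


def _single_pop_class_lengths(
    epochs: list[tuple[float, float]],
    n: int,
    n_replicates: int,
    rng: np.random.Generator,
    ploidy: int,
) -> np.ndarray:
    """Mean branch length per subtended-leaf class for one unstructured
    deme with piecewise-constant size (time-rescaled Kingman coalescent;
    compiled inner loop)."""
    starts = np.array([s for s, _ in epochs])
    pops = np.array([N for _, N in epochs])
    ends = np.append(starts[1:], np.inf)
    R = n_replicates
    exps = np.empty((n - 1, R))
    idx_i = np.empty((n - 1, R), dtype=np.int64)
    idx_j = np.empty((n - 1, R), dtype=np.int64)
    for step, k in enumerate(range(n, 1, -1)):
        exps[step] = rng.exponential(size=R)
        idx_i[step] = rng.integers(0, k, size=R)
        idx_j[step] = rng.integers(0, k - 1, size=R)
    xi = _accumulate_class_lengths(
        exps, idx_i, idx_j, starts, pops, ends, n, float(ploidy)
    )
    return xi / R


def expected_sfs(
    model: DemographicModel,
    n: int,
    n_replicates: int = 5000,
    seed: int | None = None,
    folded: bool = False,
    deme: str | None = None,
) -> np.ndarray:
    """Expected SFS probabilities by the branch-statistic estimator.

    Entry j is proportional to the mean total branch length subtending
    exactly j of n sampled lineages, normalized over polymorphic classes
    (1..n-1; for a folded spectrum, classes 1..floor(n/2)).  For a single
    unstructured deme a vectorized path is used; structured models fall
    back to the event-driven engine.
    """
    if n < 2 or n_replicates < 1:
        raise ValueError("need n >= 2 and n_replicates >= 1")
    rng = np.random.default_rng(seed)
    epochs = model.single_deme_epochs()
    if epochs is not None:
        xi = _single_pop_class_lengths(epochs, n, n_replicates, rng, model.ploidy)
    else:
        if deme is None:
            if len(model.deme_sizes) != 1:
                raise ValueError("structured model: specify the sampled deme")
            deme = next(iter(model.deme_sizes))
        xi = np.zeros(n + 1)
        for _ in range(n_replicates):
            g = simulate_genealogy(model, {deme: n}, rng)
            xi += g.class_lengths()
        xi /= n_replicates
    xi[0] = xi[n] = 0.0
    if folded:
        eta = np.zeros(n + 1)
        for j in range(1, n // 2 + 1):
            eta[j] = xi[j] + (xi[n - j] if j != n - j else 0.0)
        xi = eta
    s = xi.sum()
    return xi / s if s > 0 else xi


def expected_joint_sfs(
    model: DemographicModel,
    sample_config: dict[str, int],
    n_replicates: int = 2000,
    seed: int | None = None,
) -> dict[tuple[int, ...], float]:
    """Expected joint-SFS probabilities over the demes of ``sample_config``
    (axis order = dict insertion order), branch-statistic estimator."""
    rng = np.random.default_rng(seed)
    demes = [d for d in sample_config if sample_config[d] > 0]
    mass: dict[tuple[int, ...], float] = {}
    deme_masks = None
    for _ in range(n_replicates):
        g = simulate_genealogy(model, sample_config, rng)
        if deme_masks is None:
            deme_masks = []
            for d in demes:
                m = 0
                for i, ld in enumerate(g.leaf_demes):
                    if ld == d:
                        m |= 1 << i
                deme_masks.append(m)
        for blen, mask, _ in g.branches:
            key = tuple((mask & dm).bit_count() for dm in deme_masks)
            mass[key] = mass.get(key, 0.0) + blen
    total_cfg = tuple(sample_config[d] for d in demes)
    mass.pop(tuple(0 for _ in demes), None)
    mass.pop(total_cfg, None)
    tot = sum(mass.values())
    return {k: v / tot for k, v in mass.items()}


# ---------------------------------------------------------------------------
# synthetic data


def simulate_snp_matrix(
    model: DemographicModel,
    sample_config: dict[str, int],
    n_snps: int,
    seed: int | None = None,
    inbreeding_f: float = 0.0,
    pop_names: dict[str, str] | None = None,
    n_chroms: int = 1,
    spacing_bp: int = 1000,
    sample_prefix: str = "ind",
) -> GenotypeMatrix:
    """Simulate unlinked SNP genotypes (one segregating site per genealogy).

    Each SNP draws an independent genealogy (free recombination between
    loci), places a single mutation on a branch chosen proportional to
    its length (ascertainment: polymorphic in the full sample), and pairs
    consecutive haploids within each deme into diploid individuals.  A
    genotype-level inbreeding coefficient ``f`` is the probability that an
    individual's two alleles at a site are copies of one of them,
    producing the heterozygote deficit of a partially selfing crop.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    for d, k in sample_config.items():
        if k % 2:
            raise ValueError(f"odd haploid count for deme {d!r} with diploid output")
    rng = np.random.default_rng(seed)
    demes = [d for d in sample_config if sample_config[d] > 0]
    n_hap = sum(sample_config[d] for d in demes)
    n_ind = n_hap // 2

    sample_ids: list[str] = []
    pop_labels: dict[str, str] = {}
    for d in demes:
        label = (pop_names or {}).get(d, d)
        for i in range(sample_config[d] // 2):
            sid = f"{sample_prefix}_{d}_{i:03d}"
            sample_ids.append(sid)
            pop_labels[sid] = label

    dosage = np.zeros((n_ind, n_snps), dtype=np.int8)
    for s in range(n_snps):
        g = simulate_genealogy(model, sample_config, rng)
        lens = np.array([b for b, _, _ in g.branches])
        bi = int(rng.choice(len(lens), p=lens / lens.sum()))
        mask = g.branches[bi][1]
        hap = np.fromiter(
            ((mask >> i) & 1 for i in range(n_hap)), dtype=np.int8, count=n_hap
        )
        geno = hap[0::2] + hap[1::2]
        if inbreeding_f > 0:
            ib = rng.random(n_ind) < inbreeding_f
            which = rng.integers(0, 2, size=n_ind)
            copied = np.where(which == 0, hap[0::2], hap[1::2]) * 2
            geno = np.where(ib, copied, geno)
        dosage[:, s] = geno

    per_chrom = int(np.ceil(n_snps / n_chroms))
    chrom = np.array(
        [f"chr{1 + s // per_chrom}" for s in range(n_snps)], dtype=object
    )
    pos = np.array(
        [1 + (s % per_chrom) * spacing_bp for s in range(n_snps)], dtype=np.int64
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        chrom=chrom,
        pos=pos,
        dosage=dosage,
        ploidy=2,
    )


def simulate_sequences(
    model: DemographicModel,
    sample_config: dict[str, int],
    seq_len: int,
    mu: float,
    seed: int | None = None,
    fixed_s: int | None = None,
    sample_prefix: str = "hap",
) -> HaplotypeAlignment:
    """Simulate a haploid non-recombining locus as a 0/1 alignment.

    One genealogy underlies the whole locus; mutations are Poisson with
    mean mu*seq_len*branch_length per branch under the infinite-sites
    model.  ``fixed_s`` instead conditions on exactly S segregating sites
    placed on branches proportional to length (used for shape-controlled
    fixtures).
    """
    rng = np.random.default_rng(seed)
    g = simulate_genealogy(model, sample_config, rng)
    n = g.n_leaves
    lens = np.array([b for b, _, _ in g.branches])
    if fixed_s is not None:
        counts = rng.multinomial(fixed_s, lens / lens.sum())
    else:
        counts = rng.poisson(mu * seq_len * lens)
    cols = []
    for (blen, mask, _), c in zip(g.branches, counts):
        for _ in range(int(c)):
            cols.append(mask)
    seqs = []
    for i in range(n):
        seqs.append("".join("1" if (m >> i) & 1 else "0" for m in cols))
    ids = [f"{sample_prefix}_{i:03d}" for i in range(n)]
    return HaplotypeAlignment(
        sample_ids=ids, sequences=seqs, total_locus_length=max(seq_len, len(cols))
    )


# ---------------------------------------------------------------------------
# plain-dict (YAML/JSON) serialization


def model_to_dict(model: DemographicModel) -> dict:
    """Plain-dict form of a model, suitable for YAML/JSON round trips."""
    out: dict = {
        "deme_sizes": dict(model.deme_sizes),
        "ploidy": model.ploidy,
    }
    if model.size_changes:
        out["size_changes"] = [
            {"time": e.time, "deme": e.deme, "size": e.size}
            for e in model.size_changes
        ]
    if model.splits:
        out["splits"] = [
            {"time": s.time, "derived": list(s.derived), "ancestral": s.ancestral}
            for s in model.splits
        ]
    if model.migrations:
        out["migrations"] = [
            {
                "donor": m.donor, "recipient": m.recipient, "rate": m.rate,
                "start_time": m.start_time,
                **({"end_time": m.end_time} if math.isfinite(m.end_time) else {}),
            }
            for m in model.migrations
        ]
    if model.admixtures:
        out["admixtures"] = [
            {
                "time": a.time, "deme": a.deme,
                "parents": list(a.parents), "proportions": list(a.proportions),
            }
            for a in model.admixtures
        ]
    return out


def model_from_dict(data: dict) -> DemographicModel:
    """Inverse of :func:`model_to_dict`."""
    return DemographicModel(
        deme_sizes=dict(data["deme_sizes"]),
        size_changes=[SizeChange(**e) for e in data.get("size_changes", [])],
        splits=[Split(**s) for s in data.get("splits", [])],
        migrations=[Migration(**m) for m in data.get("migrations", [])],
        admixtures=[Admixture(**a) for a in data.get("admixtures", [])],
        ploidy=data.get("ploidy", 2),
    )
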