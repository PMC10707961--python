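"""Demographic model catalogs for composite-likelihood model selection.

Three catalogs are shipped:

* ``single_population_catalog`` — the crop's own history: constant size
  (k=1), one demographic change (k=3) and two demographic changes (k=5),
  fitted to a folded single-population SFS.
* ``hybrid_group_catalog`` — relationships among the three closely
  related wild perennials (*C. foetidissima*, *C. pedatifolia* and the
  putative hybrid *C.* x *scabridifolia*): simultaneous divergence (I),
  the hybrid taxon sister to either parent (II, III), or a true hybrid
  origin (IV), each with and without gene flow from the putative parents.
* ``crop_wild_catalog`` — the five-taxon stage on the fixed topology
  (((foetidissima, scabridifolia, pedatifolia), radicans), ficifolia):
  no gene flow (k=13) or bidirectional migration between the crop and
  one named wild relative (k=15).

Free parameters are searched log-uniformly within bounds; ordered split
times are parameterized as a first time plus positive gaps so that the
ordering holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .coalescent import Admixture, DemographicModel, Migration, SizeChange, Split

N_BOUNDS = (1e2, 1e6)
T_BOUNDS = (1e1, 1e5)
M_BOUNDS = (1e-8, 1e-2)


@dataclass
class ModelSpec:
    """A named, parameterized demographic model with search bounds.

    ``builder`` maps a complete parameter dict (free + fixed + derived)
    to a :class:`DemographicModel`; ``derive`` adds derived quantities
    (e.g. absolute second times from time gaps) to the reported params.
    """

    name: str
    description: str
    param_names: list[str]
    bounds: dict[str, tuple[float, float]]
    builder: Callable[[dict[str, float]], DemographicModel]
    fixed: dict[str, float] = field(default_factory=dict)
    derive: Callable[[dict[str, float]], dict[str, float]] | None = None
    sample_demes: list[str] | None = None  # axis order for joint spectra

    @property
    def k(self) -> int:
        return len(self.param_names)

    def full_params(self, free: dict[str, float]) -> dict[str, float]:
        p = {**self.fixed, **free}
        if self.derive is not None:
            p = {**p, **self.derive(p)}
        return p

    def build(self, free: dict[str, float]) -> DemographicModel:
        return self.builder(self.full_params(free))


# ---------------------------------------------------------------------------
# single-population catalog


def single_population_catalog(
    n_bounds: tuple[float, float] = N_BOUNDS,
    t_bounds: tuple[float, float] = T_BOUNDS,
) -> list[ModelSpec]:
    def constant(p):
        return DemographicModel({"pop": p["n_curr"]})

    def one_change(p):
        return DemographicModel(
            {"pop": p["n_curr"]},
            size_changes=[SizeChange(p["t1"], "pop", p["n_anc1"])],
        )

    def two_change(p):
        return DemographicModel(
            {"pop": p["n_curr"]},
            size_changes=[
                SizeChange(p["t1"], "pop", p["n_anc1"]),
                SizeChange(p["t1"] + p["dt2"], "pop", p["n_anc2"]),
            ],
        )

    nb, tb = n_bounds, t_bounds
    return [
        ModelSpec(
            name="constant",
            description="Constant population size",
            param_names=["n_curr"],
            bounds={"n_curr": nb},
            builder=constant,
        ),
        ModelSpec(
            name="one-change",
            description="One demographic change",
            param_names=["n_curr", "n_anc1", "t1"],
            bounds={"n_curr": nb, "n_anc1": nb, "t1": tb},
            builder=one_change,
        ),
        ModelSpec(
            name="two-change",
            description="Two demographic changes",
            param_names=["n_curr", "n_anc1", "n_anc2", "t1", "dt2"],
            bounds={"n_curr": nb, "n_anc1": nb, "n_anc2": nb, "t1": tb, "dt2": tb},
            builder=two_change,
            derive=lambda p: {"t2": p["t1"] + p["dt2"]},
        ),
    ]


# ---------------------------------------------------------------------------
# wild-relative group catalog (three taxa + outgroup)

FOE, SCA, PED, RAD, FIC, OUT = (
    "foetidissima",
    "scabridifolia",
    "pedatifolia",
    "radicans",
    "ficifolia",
    "cordata",
)


def _three_taxon_builder(topology: str):
    """Topologies over (foe, sca, ped) joined by an outgroup at t_out."""

    def build(p):
        sizes = {
            FOE: p["n_foe"],
            SCA: p["n_sca"],
            PED: p["n_ped"],
            OUT: p["n_out"],
            "anc": p["n_anc"],
            "root": p["n_root"],
        }
        splits = []
        admixtures = []
        if topology == "trichotomy":
            splits.append(Split(p["t1"], [FOE, SCA, PED], "anc"))
        elif topology == "sca-foe":
            sizes["anc0"] = p["n_anc0"]
            splits.append(Split(p["t1"], [FOE, SCA], "anc0"))
            splits.append(Split(p["t1"] + p["dt2"], ["anc0", PED], "anc"))
        elif topology == "sca-ped":
            sizes["anc0"] = p["n_anc0"]
            splits.append(Split(p["t1"], [PED, SCA], "anc0"))
            splits.append(Split(p["t1"] + p["dt2"], ["anc0", FOE], "anc"))
        elif topology == "hybrid":
            admixtures.append(
                Admixture(p["t1"], SCA, [FOE, PED], [0.5, 0.5])
            )
            splits.append(Split(p["t1"] + p["dt2"], [FOE, PED], "anc"))
        else:  # pragma: no cover
            raise ValueError(topology)
        splits.append(Split(p["t_out"], ["anc", OUT], "root"))
        migrations = []
        if p.get("m_fs", 0) > 0:
            migrations.append(Migration(FOE, SCA, p["m_fs"], end_time=p["t1"]))
        if p.get("m_ps", 0) > 0:
            migrations.append(Migration(PED, SCA, p["m_ps"], end_time=p["t1"]))
        return DemographicModel(
            sizes, splits=splits, migrations=migrations, admixtures=admixtures
        )

    return build


def hybrid_group_catalog(
    n_bounds=N_BOUNDS,
    t_bounds=T_BOUNDS,
    m_bounds=M_BOUNDS,
    t_out: float = 5e4,
    n_out: float = 2e4,
) -> list[ModelSpec]:
    """Models I-IV (x no-flow / flow) for the wild perennial group.

    Gene flow, when present, runs from both putative parents into the
    hybrid taxon until the first divergence event.  The outgroup join
    time and size are fixed.
    """
    topologies = {
        "I": ("trichotomy", "simultaneous divergence"),
        "II": ("sca-foe", "scabridifolia sister to foetidissima"),
        "III": ("sca-ped", "scabridifolia sister to pedatifolia"),
        "IV": ("hybrid", "scabridifolia hybrid of foetidissima and pedatifolia"),
    }
    out = []
    for label, (topo, desc) in topologies.items():
        base_names = ["n_foe", "n_sca", "n_ped", "n_anc", "n_root", "t1"]
        if topo in ("sca-foe", "sca-ped"):
            base_names += ["n_anc0", "dt2"]
        if topo == "hybrid":
            base_names += ["dt2"]
        bounds = {}
        for nm in base_names:
            bounds[nm] = t_bounds if nm.startswith(("t", "dt")) else n_bounds
        for flow in (False, True):
            names = list(base_names)
            b = dict(bounds)
            if flow:
                names += ["m_fs", "m_ps"]
                b["m_fs"] = b["m_ps"] = m_bounds
            out.append(
                ModelSpec(
                    name=f"{label}{'-flow' if flow else ''}",
                    description=desc + (" + gene flow into the hybrid" if flow else ""),
                    param_names=names,
                    bounds=b,
                    builder=_three_taxon_builder(topo),
                    fixed={"t_out": t_out, "n_out": n_out},
                    sample_demes=[FOE, SCA, PED],
                )
            )
    return out


# ---------------------------------------------------------------------------
# crop-wild five-taxon catalog (stage two)


def _five_taxon_builder(partner: str | None):
    """Topology (((foe, sca, ped), rad), fic) with an outgroup; optional
    bidirectional migration between the crop and one wild relative."""

    def build(p):
        t_a = p["t_a"]
        t_b = t_a + p["dt_b"]
        t_c = t_b + p["dt_c"]
        t_out = t_c + p["dt_out"]
        sizes = {
            FIC: p["n_fic"],
            RAD: p["n_rad"],
            PED: p["n_ped"],
            FOE: p["n_foe"],
            SCA: p["n_sca"],
            OUT: p["n_out"],
            "anc_fsp": p["n_anc_fsp"],
            "anc_wild": p["n_anc_wild"],
            "anc_all": p["n_anc_all"],
            "root": p["n_root"],
        }
        splits = [
            Split(t_a, [FOE, SCA, PED], "anc_fsp"),
            Split(t_b, ["anc_fsp", RAD], "anc_wild"),
            Split(t_c, ["anc_wild", FIC], "anc_all"),
            Split(t_out, ["anc_all", OUT], "root"),
        ]
        migrations = []
        if partner is not None:
            # migration active while both demes exist
            merge_time = {FOE: t_a, SCA: t_a, PED: t_a, RAD: t_b}[partner]
            end = min(t_c, merge_time)
            migrations = [
                Migration(FIC, partner, p["m_crop_to_wild"], end_time=end),
                Migration(partner, FIC, p["m_wild_to_crop"], end_time=end),
            ]
        return DemographicModel(sizes, splits=splits, migrations=migrations)

    return build


def crop_wild_catalog(
    n_bounds=N_BOUNDS,
    t_bounds=T_BOUNDS,
    m_bounds=M_BOUNDS,
    n_out: float = 2e4,
) -> list[ModelSpec]:
    """Stage-two catalog: no gene flow (I.1) or crop<->relative gene flow
    (I.2 foetidissima, I.3 scabridifolia, I.4 pedatifolia, I.5 radicans).

    k = 13 without migration (9 sizes + 4 times; the outgroup size is
    fixed) and k = 15 with the two directional rates.
    """
    size_names = [
        "n_fic", "n_rad", "n_ped", "n_foe", "n_sca",
        "n_anc_fsp", "n_anc_wild", "n_anc_all", "n_root",
    ]
    time_names = ["t_a", "dt_b", "dt_c", "dt_out"]
    partners = {
        "I.1": (None, "Absent"),
        "I.2": (FOE, "ficifolia-foetidissima"),
        "I.3": (SCA, "ficifolia-scabridifolia"),
        "I.4": (PED, "ficifolia-pedatifolia"),
        "I.5": (RAD, "ficifolia-radicans"),
    }
    out = []
    for label, (partner, desc) in partners.items():
        names = size_names + time_names
        bounds = {nm: n_bounds for nm in size_names}
        bounds.update({nm: t_bounds for nm in time_names})
        if partner is not None:
            names = names + ["m_crop_to_wild", "m_wild_to_crop"]
            bounds["m_crop_to_wild"] = bounds["m_wild_to_crop"] = m_bounds
        out.append(
            ModelSpec(
                name=label,
                description=f"Gene flow: {desc}",
                param_names=names,
                bounds=bounds,
                builder=_five_taxon_builder(partner),
                fixed={"n_out": n_out},
                derive=lambda p: {
                    "t_b": p["t_a"] + p["dt_b"],
                    "t_c": p["t_a"] + p["dt_b"] + p["dt_c"],
                    "t_out": p["t_a"] + p["dt_b"] + p["dt_c"] + p["dt_out"],
                },
                sample_demes=[FIC, RAD, PED, FOE, SCA],
            )
        )
    return out
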