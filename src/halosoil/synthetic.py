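"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's input boundary:

* :func:`gen_curve` — microcalorimetry power-time curves: flat noisy basal
  traces, and substrate-induced curves that follow A + B·exp(k·t) early and
  then saturate ("ideal": clipped exponential) or pass through the full
  lag/exponential/stationary/decline shape ("realistic": logistic growth
  term with an exponential decline factor).
* :func:`gen_community` — OTU count tables along a salinity gradient under
  a Gaussian-niche model: OTU j has a niche optimum μ_j and width σ_j on
  the salinity axis, and its expected relative abundance in a sample at
  salinity s is ∝ exp(a_j)·exp(−(s − μ_j)²/(2σ_j²)). Wide niches shift the
  *composition* along the gradient while leaving expected per-sample
  richness nearly unchanged — the qualitative dissociation the analysis is
  designed to detect. Counts are multinomial at a per-sample depth drawn
  from the sequencing-depth range; a random coalescent-style tree with
  exponential branch lengths and a dummy taxonomy (mostly bacterial, a few
  archaeal lineages) accompany the table.
* :func:`gen_chemistry` — plot metadata with EC drawn per salinity class
  inside the observed field envelope (244–4374 μS/cm) and chemistry
  covarying with EC: pH and SOC decrease with log EC, Na increases.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from halosoil.calorimetry import PowerTimeCurve
from halosoil.community import OtuTable
from halosoil.exceptions import InputError
from halosoil.salinity import classify_salinity, ec_to_salinity

_TAXONOMY_POOL_BACTERIA = [
    "Bacteria;Proteobacteria;Gammaproteobacteria;Xanthomonadales",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Salinisphaerales",
    "Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales",
    "Bacteria;Actinobacteria;Actinobacteria;Micrococcales",
    "Bacteria;Acidobacteria;Acidobacteriia;Acidobacteriales",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales",
    "Bacteria;Verrucomicrobia;Opitutae;Opitutales",
]
_TAXONOMY_POOL_ARCHAEA = [
    "Archaea;Euryarchaeota;Halobacteria;Halobacteriales",
]
_P_ARCHAEAL = 0.005  # per-OTU probability of an archaeal lineage


@dataclass
class CurveSimSpec:
    """Parameters of a simulated power-time curve.

    Units: heat flows μW/g, times hours, rates 1/h. Defaults describe a
    glucose-amended soil ampoule: a small uncoupled baseline, a growing
    fraction that saturates near ``p_asym`` and declines once the substrate
    is exhausted around ``t_decline``.
    """

    a: float = 2.0
    b: float = 0.05
    k: float = 0.35
    p_asym: float = 60.0
    t_decline: float = 30.0
    k_decline: float = 0.15
    noise_sd: float = 0.3
    dt: float = 0.1
    duration: float = 48.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.k, self.k_decline, self.dt) <= 0:
            raise InputError("rates and the sampling interval must be positive")
        if self.p_asym <= self.a:
            raise InputError("p_asym must exceed the baseline a")
        if self.b <= 0 or self.noise_sd < 0 or self.duration <= self.dt:
            raise InputError("invalid curve simulation parameters")


def gen_curve(spec: CurveSimSpec, mode: str = "realistic",
              sample_id: str = "sim") -> PowerTimeCurve:
    """Simulate one power-time curve.

    ``mode``: ``basal`` (flat baseline a + noise), ``ideal`` (exponential
    growth clipped at ``p_asym``), or ``realistic`` (logistic growth term
    with exponential decline past ``t_decline``).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    if mode == "basal":
        p = np.full_like(t, spec.a)
        curve_mode = "basal"
    elif mode == "ideal":
        p = np.minimum(spec.a + spec.b * np.exp(spec.k * t), spec.p_asym)
        curve_mode = "substrate_induced"
    elif mode == "realistic":
        cap = spec.p_asym - spec.a
        e = np.exp(spec.k * t)
        growth = cap * spec.b * e / (cap + spec.b * (e - 1.0))
        decay = np.exp(-spec.k_decline * np.maximum(0.0, t - spec.t_decline))
        p = spec.a + growth * decay
        curve_mode = "substrate_induced"
    else:
        raise InputError(f"unknown curve mode {mode!r}")
    if spec.noise_sd > 0:
        p = p + rng.normal(0.0, spec.noise_sd, size=len(t))
    return PowerTimeCurve(t=t, p=p, sample_id=sample_id, mode=curve_mode)


@dataclass
class CommunitySimSpec:
    """Parameters of the Gaussian-niche community generator.

    ``n_samples`` per salinity class; salinity draws are uniform within
    each class band (Non 0.2–1, Mild 1–4, Severe 4–12 g/kg). Niche optima
    are uniform on the salinity axis (0–12), niche widths uniform on 6–12 —
    calibrated wide enough, relative to the gradient, that rarefied
    per-sample richness is statistically flat across classes while
    composition still turns over detectably.
    Depths are uniform over ``depth_range`` (sequencing-depth envelope).
    """

    n_samples: int = 10
    n_otus: int = 300
    salinity_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Non": (0.2, 1.0), "Mild": (1.0, 4.0),
                                 "Severe": (4.0, 12.0)}
    )
    niche_optimum_range: tuple[float, float] = (0.0, 12.0)
    niche_width_range: tuple[float, float] = (6.0, 12.0)
    base_abundance_sd: float = 1.0
    depth_range: tuple[int, int] = (4500, 25000)
    seed: int | None = None


def _random_tree(otu_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Random coalescent-style topology with Exp(1) branch lengths."""
    nodes = [TreeNode(name=o, length=float(rng.exponential(1.0))) for o in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.exponential(1.0)))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def gen_community(
    spec: CommunitySimSpec,
) -> tuple[OtuTable, pd.DataFrame, TreeNode]:
    """OTU table, sample metadata and phylogeny along a salinity gradient.

    Expected relative abundance of OTU j in sample i is proportional to
    exp(a_j) · exp(−(s_i − μ_j)² / (2 σ_j²)); observed counts are
    multinomial at the sample's depth. Metadata carries ``salinity`` and
    ``sal_class`` per sample.
    """
    rng = np.random.default_rng(spec.seed)
    classes, salinities = [], []
    for cls in ("Non", "Mild", "Severe"):
        lo, hi = spec.salinity_ranges[cls]
        s = rng.uniform(lo, hi, size=spec.n_samples)
        salinities.extend(s.tolist())
        classes.extend([cls] * spec.n_samples)
    salinities = np.asarray(salinities)
    n_total = len(salinities)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_total)]
    otu_ids = [f"OTU{j + 1:04d}" for j in range(spec.n_otus)]

    mu = rng.uniform(*spec.niche_optimum_range, size=spec.n_otus)
    sigma = rng.uniform(*spec.niche_width_range, size=spec.n_otus)
    base = rng.normal(0.0, spec.base_abundance_sd, size=spec.n_otus)

    weights = np.exp(base)[None, :] * np.exp(
        -((salinities[:, None] - mu[None, :]) ** 2) / (2.0 * sigma[None, :] ** 2)
    )
    probs = weights / weights.sum(axis=1, keepdims=True)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n_total)
    counts = np.array(
        [rng.multinomial(d, p) for d, p in zip(depths, probs)], dtype=np.int64
    )

    lineage_idx = rng.integers(0, len(_TAXONOMY_POOL_BACTERIA), size=spec.n_otus)
    archaeal = rng.random(spec.n_otus) < _P_ARCHAEAL
    taxonomy = {
        o: (_TAXONOMY_POOL_ARCHAEA[0] if arch else _TAXONOMY_POOL_BACTERIA[li])
        for o, li, arch in zip(otu_ids, lineage_idx, archaeal)
    }

    table = OtuTable(counts, sample_ids, otu_ids, taxonomy)
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "salinity": salinities, "sal_class": classes}
    )
    tree = _random_tree(otu_ids, rng)
    return table, meta, tree


# class envelopes in μS/cm; the Non ceiling sits just under the EC at which
# the calibrated conversion crosses 1 g/kg (≈397.1), so drawn EC and derived
# class always agree
_EC_RANGES = {"Non": (244.0, 397.0), "Mild": (400.0, 800.0),
              "Severe": (2400.0, 4374.0)}


def gen_chemistry(n_per_class: int = 10, seed: int | None = None) -> pd.DataFrame:
    """Plot metadata with EC-linked chemistry.

    EC is uniform within the class envelopes (overall 244–4374 μS/cm);
    pH = 8.6 − 0.9·log10(EC/244) + N(0, 0.1), Na = 0.12·(EC/244) +
    N(0, 0.1) g/kg, and SOC, AN and dehydrogenase decrease with log EC.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for cls in ("Non", "Mild", "Severe"):
        lo, hi = _EC_RANGES[cls]
        for _ in range(n_per_class):
            i += 1
            ec = float(rng.uniform(lo, hi))
            le = np.log10(ec / 244.0)
            sal = ec_to_salinity(ec)
            rows.append(
                {
                    "plot_id": f"P{i:02d}",
                    "ec_uS_cm": ec,
                    "salinity_g_kg": round(sal, 2),
                    "sal_class": classify_salinity(sal).value,
                    "pH": 8.6 - 0.9 * le + rng.normal(0.0, 0.1),
                    "SOC": max(0.5, 12.0 - 6.0 * le + rng.normal(0.0, 0.5)),
                    "Na": max(0.01, 0.12 * ec / 244.0 + rng.normal(0.0, 0.1)),
                    "AN": max(1.0, 80.0 - 25.0 * le + rng.normal(0.0, 5.0)),
                    "AP": max(0.5, 20.0 + rng.normal(0.0, 2.0)),
                    "K": max(10.0, 150.0 + rng.normal(0.0, 15.0)),
                    "dehydrogenase": max(0.1, 25.0 - 12.0 * le + rng.normal(0.0, 1.5)),
                }
            )
    return pd.DataFrame(rows)
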