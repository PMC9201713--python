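"""Synthetic cohort generation with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a marker-block immune signature matrix (an LM22 stand-in), bulk
mixtures with Dirichlet cell fractions drawn per planted immune subtype,
additive/multiplicative batch effects across sub-cohorts, exponential
survival with proportional subtype hazards, Poisson mutation counts tied to
a planted per-sample score, and cell-line drug-response tables whose
log-IC50 is a sparse linear function of expression.

Every generator is deterministic under a fixed seed, and every planted
quantity is recorded in a :class:`CohortTruth` ledger so recovery tests can
compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

DEFAULT_CELL_TYPES = 22

# Immune cell labels mirroring the usual 22-type reference panel.
LM22_LABELS = [
    "B_cells_naive", "B_cells_memory", "Plasma_cells",
    "T_cells_CD8", "T_cells_CD4_naive", "T_cells_CD4_memory_resting",
    "T_cells_CD4_memory_activated", "T_cells_follicular_helper",
    "T_cells_regulatory", "T_cells_gamma_delta",
    "NK_cells_resting", "NK_cells_activated",
    "Monocytes", "Macrophages_M0", "Macrophages_M1", "Macrophages_M2",
    "Dendritic_cells_resting", "Dendritic_cells_activated",
    "Mast_cells_resting", "Mast_cells_activated",
    "Eosinophils", "Neutrophils",
]


@dataclass
class CohortTruth:
    """Ground-truth ledger for a simulated cohort.

    Attributes
    ----------
    fractions : pd.DataFrame
        samples x cell_types; every row on the simplex.
    subtype : pd.Series
        Planted immune subtype label per sample.
    batch : pd.Series
        Sub-cohort (batch) label per sample.
    batch_shift : dict
        Per-batch ``{"offset": per-gene additive shift (log2 scale),
        "scale": multiplicative factor (log2 scale)}``.
    hazard_multiplier : dict
        Positive proportional-hazards multiplier per subtype.
    hot_score : pd.Series
        Planted per-sample immune-hot score (sum of fractions over the
        hot cell types); drives TMB and response plantings.
    tmb_true : pd.Series
        Planted mutations-per-megabase per sample.
    drug_effects : dict
        Per-drug coefficient vector over genes (only for drug cohorts).
    """

    fractions: pd.DataFrame
    subtype: pd.Series
    batch: pd.Series
    batch_shift: dict = field(default_factory=dict)
    hazard_multiplier: dict = field(default_factory=dict)
    hot_score: pd.Series | None = None
    tmb_true: pd.Series | None = None
    drug_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        row_sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")
        for m in self.hazard_multiplier.values():
            if m <= 0:
                raise ValueError("hazard multipliers must be positive")
        if self.tmb_true is not None and (self.tmb_true < 0).any():
            raise ValueError("tmb_true must be non-negative")

    def to_dict(self) -> dict:
        frac = self.fractions
        d = {
            "fractions": {"index": list(frac.index),
                          "columns": list(frac.columns),
                          "data": frac.to_numpy().tolist()},
            "subtype": self.subtype.to_dict(),
            "batch": self.batch.to_dict(),
            "batch_shift": {
                b: {"offset": list(np.atleast_1d(v["offset"]).astype(float)),
                    "scale": float(v["scale"])}
                for b, v in self.batch_shift.items()
            },
            "hazard_multiplier": dict(self.hazard_multiplier),
            "hot_score": None if self.hot_score is None
            else self.hot_score.to_dict(),
            "tmb_true": None if self.tmb_true is None
            else self.tmb_true.to_dict(),
            "drug_effects": {k: {g: float(x) for g, x in v.items()}
                             for k, v in self.drug_effects.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        return cls(
            fractions=pd.DataFrame(d["fractions"]["data"],
                                   index=d["fractions"]["index"],
                                   columns=d["fractions"]["columns"]),
            subtype=pd.Series(d["subtype"]),
            batch=pd.Series(d["batch"]),
            batch_shift={
                b: {"offset": np.asarray(v["offset"]), "scale": v["scale"]}
                for b, v in d.get("batch_shift", {}).items()
            },
            hazard_multiplier=d.get("hazard_multiplier", {}),
            hot_score=None if d.get("hot_score") is None
            else pd.Series(d["hot_score"]),
            tmb_true=None if d.get("tmb_true") is None
            else pd.Series(d["tmb_true"]),
            drug_effects=d.get("drug_effects", {}),
        )


def make_signature_matrix(n_genes: int = 220,
                          n_cell_types: int = DEFAULT_CELL_TYPES,
                          seed: int = 0,
                          marker_fold: float = 10.0,
                          background_mean: float = 2.0) -> pd.DataFrame:
    """Build a marker-block immune signature matrix.

    Each cell type receives a disjoint block of marker genes whose mean
    expression in that type is ``marker_fold`` times the log-normal
    background. The block design guarantees identifiability, so a
    deconvolution failure on this matrix indicates a bug rather than an
    ill-posed problem.

    Parameters
    ----------
    n_genes, n_cell_types : int
        Matrix dimensions; requires ``n_genes >= n_cell_types >= 2``
        (fewer genes than cell types makes deconvolution under-determined).
    marker_fold : float
        Fold elevation of marker genes over background (>= 8 recommended).
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_genes < n_cell_types:
        raise ValueError(
            f"n_genes={n_genes} < n_cell_types={n_cell_types}: "
            "deconvolution would be under-determined")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    if n_cell_types <= len(LM22_LABELS):
        cell_types = LM22_LABELS[:n_cell_types]
    else:
        cell_types = [f"CT{i:02d}" for i in range(n_cell_types)]

    # log-normal background, markers elevated by marker_fold
    base = rng.lognormal(mean=np.log(background_mean), sigma=0.25,
                         size=(n_genes, n_cell_types))
    block = n_genes // n_cell_types
    for c in range(n_cell_types):
        rows = slice(c * block, (c + 1) * block)
        base[rows, c] *= marker_fold * rng.lognormal(0.0, 0.1,
                                                     size=(block,))
    return pd.DataFrame(base, index=genes, columns=cell_types)


def marker_blocks(signature: pd.DataFrame) -> dict[str, list[str]]:
    """Recover the marker-gene block of each cell type from a block-design
    signature matrix (genes whose expression in the type exceeds 4x the
    row median)."""
    med = signature.median(axis=1)
    out: dict[str, list[str]] = {}
    for ct in signature.columns:
        out[ct] = signature.index[(signature[ct] > 4 * med)].tolist()
    return out


DEFAULT_SUBTYPE_PROFILES = None  # built lazily against a signature


def default_subtype_profiles(cell_types: list[str]) -> dict[str, np.ndarray]:
    """Three immune subtypes as Dirichlet concentration vectors.

    Subtype II concentrates on the cytotoxic/hot axis (CD8 T cells, M1
    macrophages, plasma cells, activated memory CD4), subtype I on the
    myeloid/resting axis (M2, neutrophils, resting mast, resting CD4),
    subtype III on the naive/cold axis (naive B, naive CD4, resting NK,
    M0, activated mast). Cell types absent from the panel fall back to a
    uniform low concentration.
    """
    hot = {"T_cells_CD8", "Macrophages_M1", "Plasma_cells",
           "T_cells_CD4_memory_activated", "B_cells_memory",
           "Dendritic_cells_activated"}
    myeloid = {"Macrophages_M2", "Neutrophils", "Mast_cells_resting",
               "T_cells_CD4_memory_resting", "NK_cells_activated",
               "T_cells_gamma_delta"}
    cold = {"B_cells_naive", "T_cells_CD4_naive", "NK_cells_resting",
            "Macrophages_M0", "Mast_cells_activated"}

    def conc(enriched: set[str]) -> np.ndarray:
        v = np.full(len(cell_types), 0.6)
        for i, ct in enumerate(cell_types):
            if ct in enriched:
                v[i] = 8.0
        return v

    return {"I": conc(myeloid), "II": conc(hot), "III": conc(cold)}


HOT_CELL_TYPES = ["T_cells_CD8", "Macrophages_M1", "Plasma_cells",
                  "T_cells_CD4_memory_activated", "B_cells_memory",
                  "Dendritic_cells_activated"]


def hot_cold_profiles(cell_types: list[str]) -> dict[str, np.ndarray]:
    """Two-subtype design: an immune-hot half and an immune-cold half,
    for experiments where the planted truth is binary."""
    prof = default_subtype_profiles(cell_types)
    return {"hot": prof["II"], "cold": prof["III"]}


def simulate_bulk_cohort(signature: pd.DataFrame,
                         n_samples: int = 200,
                         subtype_profiles: dict | None = None,
                         noise_sd: float = 0.1,
                         batch_spec: dict | None = None,
                         hazard_multiplier: dict | None = None,
                         tmb_base: float = 1.0,
                         tmb_slope: float = 6.0,
                         seed: int = 0) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a bulk expression cohort from a signature matrix.

    Expression is ``signature @ fractions`` plus Gaussian noise with
    standard deviation ``noise_sd`` times the gene mean, clipped at zero.
    Fractions are Dirichlet draws per planted subtype. Batch effects
    (additive offset + multiplicative scale, applied on the log2(x+1)
    scale, emulating the technical shifts seen when merging cohorts) are
    applied per ``batch_spec``; the hot score and a linked TMB truth are
    recorded in the ledger.

    Parameters
    ----------
    subtype_profiles : dict label -> Dirichlet concentration vector
        Defaults to three subtypes (I myeloid/resting, II hot, III cold).
    batch_spec : dict or None
        ``{"n_batches": 2, "shift": 5.0, "scale": 1.5, "offset_sd": 0.0}``;
        batch 1 is the reference, later batches get the planted shift.
    tmb_base, tmb_slope : float
        Planted TMB per sample: ``tmb_base + tmb_slope * hot_score``
        (mut/Mb), so TMB is positively coupled to the immune-hot axis.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    cell_types = list(signature.columns)
    if subtype_profiles is None:
        subtype_profiles = default_subtype_profiles(cell_types)
    if not subtype_profiles:
        raise ValueError("subtype_profiles must not be empty")
    for name, conc in subtype_profiles.items():
        if len(np.atleast_1d(conc)) != len(cell_types):
            raise ValueError(
                f"profile {name!r} length != number of cell types")
    if hazard_multiplier is None:
        hazard_multiplier = {"I": 1.0, "II": 0.6, "III": 2.0}
        hazard_multiplier = {k: hazard_multiplier.get(k, 1.0)
                             for k in subtype_profiles}

    labels = list(subtype_profiles)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    subtype = pd.Series(
        [labels[i % len(labels)] for i in range(n_samples)],
        index=samples, name="subtype")

    frac = np.vstack([
        rng.dirichlet(np.asarray(subtype_profiles[subtype.iloc[i]],
                                 dtype=float))
        for i in range(n_samples)])
    fractions = pd.DataFrame(frac, index=samples, columns=cell_types)

    clean = signature.to_numpy() @ frac.T          # genes x samples
    gene_mean = clean.mean(axis=1, keepdims=True)
    if noise_sd > 0:
        clean = clean + rng.normal(
            0.0, 1.0, size=clean.shape) * (noise_sd * gene_mean)
    expr = np.clip(clean, 0.0, None)

    n_batches = (batch_spec or {}).get("n_batches", 1)
    # randomized balanced assignment so batch is not confounded with the
    # (cyclic) subtype layout
    batch_idx = rng.permutation(np.arange(n_samples) % n_batches)
    batch = pd.Series([f"B{b + 1}" for b in batch_idx],
                      index=samples, name="batch")
    batch_shift: dict = {}
    if batch_spec and n_batches > 1:
        shift = float(batch_spec.get("shift", 0.0))
        scale = float(batch_spec.get("scale", 1.0))
        offset_sd = float(batch_spec.get("offset_sd", 0.0))
        log_expr = np.log2(expr + 1.0)
        grand = log_expr.mean(axis=1, keepdims=True)
        for b in range(1, n_batches):
            name = f"B{b + 1}"
            offsets = shift + (rng.normal(0.0, offset_sd, size=expr.shape[0])
                               if offset_sd > 0 else np.zeros(expr.shape[0]))
            cols = (batch == name).to_numpy()
            log_expr[:, cols] = (grand
                                 + scale * (log_expr[:, cols] - grand)
                                 + offsets[:, None])
            batch_shift[name] = {"offset": offsets, "scale": scale}
        expr = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
        batch_shift["B1"] = {"offset": np.zeros(expr.shape[0]), "scale": 1.0}

    expr_df = pd.DataFrame(expr, index=signature.index, columns=samples)

    hot_cols = [c for c in HOT_CELL_TYPES if c in cell_types]
    hot_score = (fractions[hot_cols].sum(axis=1) if hot_cols
                 else fractions.iloc[:, 0] * 0.0)
    hot_score.name = "hot_score"
    tmb_true = (tmb_base + tmb_slope * hot_score).clip(lower=0.0)
    tmb_true.name = "tmb_true"

    truth = CohortTruth(fractions=fractions, subtype=subtype, batch=batch,
                        batch_shift=batch_shift,
                        hazard_multiplier=dict(hazard_multiplier),
                        hot_score=hot_score, tmb_true=tmb_true)
    return expr_df, truth


def simulate_survival(truth: CohortTruth,
                      baseline_hazard: float = 0.02,
                      censor_rate: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Draw exponential survival times with proportional subtype hazards.

    Event times are exponential with rate ``baseline_hazard *
    hazard_multiplier(subtype)`` (per month). Censoring is an independent
    exponential whose rate is calibrated so the expected censored
    proportion is ``censor_rate``; observed time is the minimum of the two.

    Returns a clinical table (sample, time, event, subtype, age, stage).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = truth.subtype.index
    mult = truth.subtype.map(
        lambda s: truth.hazard_multiplier.get(s, 1.0)).to_numpy(dtype=float)
    rates = baseline_hazard * mult
    event_t = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        # P(censor first) = lc / (lc + le); calibrate vs mean event rate
        lc = censor_rate / (1.0 - censor_rate) * rates.mean()
        censor_t = rng.exponential(1.0 / lc, size=len(samples))
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(len(samples), dtype=int)
    return pd.DataFrame({
        "time": time,
        "event": event,
        "subtype": truth.subtype.to_numpy(),
        "age": rng.integers(30, 85, size=len(samples)),
        "stage": rng.choice(["I", "II", "III"], size=len(samples),
                            p=[0.3, 0.5, 0.2]),
    }, index=pd.Index(samples, name="sample"))


NONSILENT_CLASSES = [
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation",
]


def simulate_maf(truth: CohortTruth,
                 genes: list[str] | None = None,
                 exome_mb: float = 38.0,
                 silent_fraction: float = 0.25,
                 seed: int = 0) -> pd.DataFrame:
    """Generate somatic mutation records consistent with the planted TMB.

    Per sample the non-silent mutation count is Poisson with mean
    ``tmb_true * exome_mb``, distributed uniformly over ``genes``; an
    additional Poisson stream of Silent records (mean ``silent_fraction``
    of the non-silent mean) exercises the variant-class filter downstream.
    """
    if truth.tmb_true is None:
        raise ValueError("truth has no tmb_true")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"MUT{i:03d}" for i in range(50)]
    genes = list(genes)
    rows = []
    for sample, tmb in truth.tmb_true.items():
        n_ns = rng.poisson(tmb * exome_mb)
        n_sil = rng.poisson(silent_fraction * tmb * exome_mb)
        for kind, n in (("nonsilent", n_ns), ("silent", n_sil)):
            if n == 0:
                continue
            gs = rng.choice(genes, size=n)
            classes = (rng.choice(NONSILENT_CLASSES, size=n,
                                  p=_NS_CLASS_P)
                       if kind == "nonsilent"
                       else np.full(n, "Silent"))
            chroms = rng.integers(1, 23, size=n)
            starts = rng.integers(1, 2_000_000, size=n)
            for g, cl, ch, st in zip(gs, classes, chroms, starts):
                rows.append((g, cl, sample, str(ch), int(st)))
    return pd.DataFrame(rows, columns=[
        "Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode",
        "Chromosome", "Start_Position"])


# missense-dominated class mix, roughly matching exome sequencing studies
_NS_CLASS_P = np.array([0.62, 0.08, 0.07, 0.06, 0.03, 0.03, 0.07,
                        0.01, 0.03])
_NS_CLASS_P = _NS_CLASS_P / _NS_CLASS_P.sum()


def simulate_drug_training(n_lines: int = 200,
                           n_genes: int = 100,
                           n_drugs: int = 20,
                           noise_sd: float = 0.2,
                           k_nonzero: int = 5,
                           effect_scale: float = 1.0,
                           null_drugs: list[str] | None = None,
                           gene_names: list[str] | None = None,
                           seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cell-line drug-response training set.

    Expression per line is i.i.d. log-normal; each drug's log-IC50 is a
    sparse linear function of expression (``k_nonzero`` active genes,
    coefficients ~ N(0, effect_scale)) plus N(0, noise_sd) noise. Drugs
    named in ``null_drugs`` get a zero coefficient vector.

    Returns (expression genes x lines, log-IC50 lines x drugs,
    drug_effects {drug: {gene: beta}}).
    """
    if n_lines < 3:
        raise ValueError("need at least 3 training lines")
    if not (n_lines > n_drugs >= 1):
        raise ValueError("require n_lines > n_drugs >= 1")
    rng = np.random.default_rng(seed)
    if gene_names is not None:
        if len(gene_names) != n_genes:
            raise ValueError("gene_names length must equal n_genes")
        genes = list(gene_names)
    else:
        genes = [f"DG{i:03d}" for i in range(n_genes)]
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    drugs = [f"drug_{i:02d}" for i in range(n_drugs)]
    X = rng.lognormal(mean=1.0, sigma=0.6, size=(n_genes, n_lines))
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    effects: dict[str, dict[str, float]] = {}
    Y = np.empty((n_lines, n_drugs))
    null = set(null_drugs or [])
    for j, d in enumerate(drugs):
        beta = np.zeros(n_genes)
        if d not in null:
            idx = rng.choice(n_genes, size=k_nonzero, replace=False)
            beta[idx] = rng.normal(0.0, effect_scale, size=k_nonzero)
        eps = rng.normal(0.0, noise_sd, size=n_lines) if noise_sd > 0 else 0.0
        Y[:, j] = Xz.T @ beta + eps
        effects[d] = {genes[i]: float(beta[i]) for i in np.nonzero(beta)[0]}
    expr = pd.DataFrame(X, index=genes, columns=lines)
    ic50 = pd.DataFrame(Y, index=lines, columns=drugs)
    return expr, ic50, effects


def make_gene_sets(signature: pd.DataFrame,
                   n_immune_types: int | None = None
                   ) -> dict[str, list[str]]:
    """Build immune/stromal gene panels from a block-design signature:
    the immune panel is the union of marker blocks of the first
    ``n_immune_types`` cell types (default: half the panel), the
    stromal panel the rest."""
    blocks = marker_blocks(signature)
    cts = list(signature.columns)
    if n_immune_types is None:
        n_immune_types = max(1, len(cts) // 2)
    immune = [g for ct in cts[:n_immune_types] for g in blocks[ct]]
    stromal = [g for ct in cts[n_immune_types:] for g in blocks[ct]]
    return {"IMMUNE": immune, "STROMAL": stromal}
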