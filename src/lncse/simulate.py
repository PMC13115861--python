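"""Seeded generator of every pipeline input, with known ground truth.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — split-probe contact peak fractions with
reproducible planted peaks and fraction-private noise, per-sample
super-enhancer BEDs satisfying the consensus support rules by construction,
a multi-lncRNA correlation-peak table with confirming peaks planted inside
Ψ-designated SEs and decoys inside Ω SEs, and a tumor cohort with a latent
focal-lncRNA activity factor plus a purity confound — so every stage and
both permutation tests can be exercised offline against planted truth.

Scales are desk-sized (3 chromosomes x 2 Mb, ~170 contact peaks, ~30 SEs,
~250 genes, 120 tumor + 20 normal cohort samples) so a full pipeline run
plus 1000-iteration permutation tests completes in minutes.

All placements are deterministic functions of (config, seed).  The planted
layout keeps independently placed features at least 3 kb apart (more for
features whose interaction radius is larger, e.g. sample-private noise SEs
vs. the 12.5 kb stitching distance), so intended overlaps are the only
overlaps and the ground truth is exact rather than probabilistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import ChromSizes, IntervalSet
from . import io as lio

FOCAL_LNC = "LNC_FOCAL"


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    block_spacing: int = 200_000
    block_offset: int = 60_000
    # contact layer
    n_replicates: int = 3
    contact_width: tuple[int, int] = (300, 600)
    n_background_contacts: int = 140  # supported by all replicates
    n_tworep_contacts: int = 20  # supported by exactly two replicates
    n_singlerep_contacts: int = 10  # one replicate only: must not survive
    noise_peaks_per_fraction: int = 40  # fraction-private noise
    jitter: int = 50
    pad: int = 250
    n_blacklist_zones: int = 3
    n_artifact_peaks: int = 5  # planted inside blacklist zones
    # SE layer
    se_width: tuple[int, int] = (12_000, 20_000)
    se_boundary_jitter: int = 500
    fragment_prob: float = 0.35
    fragment_gap: int = 10_000  # strictly below the 12,500 bp stitch distance
    n_noise_ses_per_sample: int = 2
    # correlation layer
    corr_width: tuple[int, int] = (200, 400)
    n_background_corr: int = 120  # focal peaks outside SEs
    n_background_confirmed: int = 30  # subset placed onto background contacts
    n_extra_lncrnas: int = 49
    extra_lnc_max_count: int = 10
    # genes / expression
    n_filler_genes: int = 150
    n_normalblock_genes: int = 30
    gene_width: int = 2_000
    n_tumor: int = 120
    n_normal_cohort: int = 20
    n_purity_missing: int = 10
    beta_pos: float = 0.5
    beta_neg: float = -0.4
    gamma_gene: float = 0.3
    gamma_focal: float = 0.4
    noise_sd: float = 0.5
    focal_noise_sd: float = 0.2
    tumor_shift_up: float = 1.2
    tumor_shift_down: float = -1.0
    focal_tumor_shift: float = 1.9
    cellline_lfc: float = 1.5
    cellline_sd: float = 0.2
    n_cellline_reps: int = 4


# ---------------------------------------------------------------------------
# placement bookkeeping
# ---------------------------------------------------------------------------


class _Layout:
    """Tracks inflated occupied intervals per chrom; rejection-samples gaps."""

    def __init__(self, sizes: dict[str, int], rng: np.random.Generator):
        self.sizes = sizes
        self.rng = rng
        self.occ: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def register(self, chrom: str, start: int, end: int, inflate: int = 1_500) -> None:
        self.occ[chrom].append((max(0, start - inflate), end + inflate))

    def place(self, width: int, inflate: int = 1_500, chrom: str | None = None,
              max_tries: int = 20_000) -> tuple[str, int, int]:
        chroms = sorted(self.sizes) if chrom is None else [chrom]
        for _ in range(max_tries):
            c = chroms[int(self.rng.integers(len(chroms)))]
            s = int(self.rng.integers(0, self.sizes[c] - width + 1))
            e = s + width
            lo, hi = s - inflate, e + inflate
            if any(a < hi and lo < b for a, b in self.occ[c]):
                continue
            self.register(c, s, e, inflate)
            return c, s, e
        raise RuntimeError("could not place a feature; the toy genome is over-committed")


# ---------------------------------------------------------------------------
# planted design
# ---------------------------------------------------------------------------

# per-chromosome block class assignment (block index -> class)
_BLOCK_PLAN = {
    "chr1": ["cancer", "shared", "normal", "cancer", "normal", "normal",
             "cancer", "shared", "normal", "cancer"],
    "chr2": ["normal", "cancer", "shared", "normal", "cancer", "normal",
             "normal", "cancer", "shared", "normal"],
    "chr3": ["cancer", "shared", "cancer", "shared", "cancer", "cancer",
             "normal", "normal"],
}

# cancer-specific SEs in placement order get these roles
_CANCER_ROLES = [
    "psi_compound",   # c0: two confirmed (mark,sign) pairs; 4 targets
    "omega_decoy",    # c1: body corr peaks without contact support + contacts
    "psi_concordant", # c2: confirmed peak at an overlapping target's TSS
    "omega_tss",      # c3: confirmed peak at a distal target's TSS only
    "omega_decoy2",   # c4
    "psi_no_target",  # c5: Psi with no expressed gene in the window
    "omega_tss2",     # c6
    "omega_contact",  # c7: contacts but neither body nor TSS marks
    "psi_nonsig",     # c8: Psi whose only target is not DE-significant
    "omega_plain",    # c9
    "omega_plain2",   # c10
    "psi_boundary",   # c11: window / TPM boundary-case targets
]

_PSI_MARKS = {
    "psi_compound": [("H3K4me1", "+"), ("H3K4me3", "+")],
    "psi_concordant": [("H3K4me1", "+")],
    "psi_no_target": [("H3K4me3", "-")],
    "psi_nonsig": [("H3K4me1", "+")],
    "psi_boundary": [("H3K27me3", "+")],
}
_DECOY_MARKS = {"omega_decoy": ("H3K4me1", "+"), "omega_decoy2": ("H3K27ac", "+")}
_TSS_MARKS = {"omega_tss": ("H3K4me1", "+"), "omega_tss2": ("H3K4me3", "+")}


def _se_key(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class _PlantedSE:
    chrom: str
    start: int
    end: int
    condition_class: str  # cancer-specific / normal-specific / shared
    role: str | None = None
    marks: list = field(default_factory=list)
    contacts: list = field(default_factory=list)  # (start, end) confirmed+extra
    corr: list = field(default_factory=list)  # (start, end, mark, sign, confirmed)

    @property
    def key(self) -> str:
        return _se_key(self.chrom, self.start, self.end)


def _plant_ses(cfg: SimulationConfig, rng: np.random.Generator, layout: _Layout) -> list[_PlantedSE]:
    ses: list[_PlantedSE] = []
    cancer_i = 0
    for chrom, plan in _BLOCK_PLAN.items():
        for k, cls in enumerate(plan):
            base = cfg.block_offset + k * cfg.block_spacing
            start = base + int(rng.integers(0, 15_000))
            width = int(rng.integers(*cfg.se_width))
            se = _PlantedSE(chrom, start, start + width, {
                "cancer": "cancer-specific", "normal": "normal-specific", "shared": "shared"
            }[cls])
            if cls == "cancer":
                se.role = _CANCER_ROLES[cancer_i]
                cancer_i += 1
            ses.append(se)
            layout.register(chrom, start, start + width)
    # the boundary-case SE sits in the chr3 tail with >100 kb clearance on
    # both sides of its target window (the last regular chr3 block ends near
    # 1.49 Mb and its collar genes stay left of ~1.53 Mb)
    start, width = 1_640_000, 15_000
    se = _PlantedSE("chr3", start, start + width, "cancer-specific", role="psi_boundary")
    ses.append(se)
    layout.register("chr3", start, start + width)
    return ses


def _plant_se_internals(cfg: SimulationConfig, ses: list[_PlantedSE]) -> None:
    """Deterministic in-SE layout of contact and correlation peaks."""
    for se in ses:
        role = se.role
        if role is None:
            continue
        a = se.start + 1_500  # site A
        b = se.start + 4_000  # site B
        right = se.end - 3_000
        if role.startswith("psi"):
            marks = _PSI_MARKS[role]
            se.marks = list(marks)
            se.contacts.append((a, a + 500))
            se.corr.append((a + 100, a + 400, marks[0][0], marks[0][1], True))
            if len(marks) > 1:
                se.contacts.append((b, b + 500))
                se.corr.append((b + 100, b + 400, marks[1][0], marks[1][1], True))
            else:
                # second contact peak: plants the higher contact density at
                # Ψ SEs (median 2 vs 1 against contacted Ω SEs)
                se.contacts.append((right, right + 500))
        elif role in _DECOY_MARKS:
            mark, sign = _DECOY_MARKS[role]
            se.corr.append((a, a + 300, mark, sign, False))
            se.contacts.append((right, right + 500))
        elif role in ("omega_tss", "omega_tss2", "omega_contact"):
            se.contacts.append((right, right + 500))
        # omega_plain / omega_plain2: nothing inside


_GENE_CATEGORIES = ("triple", "fail_cellline", "fail_cohort", "fail_coexpr",
                    "nonsig", "neutral")


def _plant_genes(cfg: SimulationConfig, ses: list[_PlantedSE]) -> list[dict]:
    """Explicit target genes around the cancer-specific SEs.

    Returns dicts with gene_id, coordinates, strand, biotype, tpm_cancer,
    category, anchor SE key, and whether the association is intended.
    """
    by_role = {se.role: se for se in ses if se.role}
    genes: list[dict] = []

    def add(gid, se, start, strand, tpm, category, associated, width=None):
        width = width or cfg.gene_width
        genes.append({
            "gene_id": gid, "symbol": gid, "chrom": se.chrom,
            "start": int(start), "end": int(start + width), "strand": strand,
            "biotype": "protein_coding", "tpm_cancer": float(tpm),
            "category": category, "anchor": se.key, "associated": associated,
        })

    c0 = by_role["psi_compound"]
    add("G_C0_T0", c0, c0.end - 2_000, "+", 20.0, "triple", True, width=5_000)
    add("G_C0_T1", c0, c0.end + 15_000, "+", 8.0, "fail_cellline", True)
    add("G_C0_T2", c0, c0.end + 30_000, "-", 12.0, "fail_coexpr", True)
    add("G_C0_T3", c0, c0.end + 45_000, "+", 6.0, "triple", True)

    c2 = by_role["psi_concordant"]
    site_a_corr = c2.corr[0]
    add("G_C2_CONC", c2, site_a_corr[0] + 100, "+", 15.0, "triple", True, width=6_000)
    add("G_C2_T1", c2, c2.start - 20_000, "+", 6.0, "fail_cohort", True)

    c8 = by_role["psi_nonsig"]
    add("G_C8_T0", c8, c8.end + 25_000, "+", 9.0, "nonsig", True)

    c11 = by_role["psi_boundary"]
    add("G_C11_B100K", c11, c11.end + 100_000, "+", 5.0, "triple", True)
    add("G_C11_B100001", c11, c11.end + 100_001, "+", 5.0, "triple", False)
    add("G_C11_TPM1", c11, c11.start + 2_000, "+", 1.0, "triple", False)
    add("G_C11_T1", c11, c11.end + 30_000, "-", 7.0, "fail_coexpr", True)

    c3 = by_role["omega_tss"]
    add("G_C3_TSS", c3, c3.end + 25_000, "+", 10.0, "neutral", True)
    c6 = by_role["omega_tss2"]
    # minus-strand gene left of the SE: TSS at its end-1
    add("G_C6_TSS", c6, c6.start - 27_000, "-", 8.0, "neutral", True)
    return genes


def _plant_tss_corr(cfg: SimulationConfig, ses: list[_PlantedSE], genes: list[dict]) -> list[dict]:
    """Confirmed correlation+contact pairs at the TSS of the Ω-TSS genes."""
    by_id = {g["gene_id"]: g for g in genes}
    by_role = {se.role: se for se in ses if se.role}
    out = []
    for role, gid in (("omega_tss", "G_C3_TSS"), ("omega_tss2", "G_C6_TSS")):
        g = by_id[gid]
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        mark, sign = _TSS_MARKS[role]
        out.append({
            "se_key": by_role[role].key, "gene_id": gid,
            "contact": (g["chrom"], tss - 200, tss + 300),
            "corr": (g["chrom"], tss - 100, tss + 200, mark, sign),
            "mark": mark, "sign": sign,
        })
    return out


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------


def _narrowpeak_frame(rows: list[tuple[str, int, int]], prefix: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df["name"] = [f"{prefix}_{i}" for i in range(len(df))]
    df["score"] = 0
    df["strand"] = "."
    df["signal"] = 5.0
    df["pvalue"] = 10.0
    df["qvalue"] = 5.0
    df["summit"] = (df["end"] - df["start"]) // 2
    return df


def _jitter_peak(rng: np.random.Generator, chrom: str, s: int, e: int, j: int) -> tuple[str, int, int]:
    d = int(rng.integers(-j, j + 1))
    return chrom, max(0, s + d), e + d


def generate_contact_fractions(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    layout: _Layout,
    ses: list[_PlantedSE],
    tss_pairs: list[dict],
    out_dir: Path,
) -> dict:
    """Emit per-replicate odd/even/input narrowPeak files and the blacklist.

    Planted consensus peaks appear (jittered <= ``cfg.jitter``) in both
    fractions of all (or exactly two) replicates; noise peaks are private to
    one fraction of one replicate; artifact peaks sit inside blacklist zones
    in every fraction and must be removed by the blacklist filter.
    """
    wlo, whi = cfg.contact_width
    blacklist = [layout.place(10_000, inflate=2_000) for _ in range(cfg.n_blacklist_zones)]

    all_rep: list[tuple[str, int, int]] = []
    for se in ses:
        all_rep.extend((se.chrom, s, e) for s, e in se.contacts)
    for pair in tss_pairs:
        all_rep.append(tuple(pair["contact"]))
    for _ in range(cfg.n_background_contacts):
        c, s, e = layout.place(int(rng.integers(wlo, whi)))
        all_rep.append((c, s, e))
    two_rep = [layout.place(int(rng.integers(wlo, whi))) for _ in range(cfg.n_tworep_contacts)]
    one_rep = [layout.place(int(rng.integers(wlo, whi))) for _ in range(cfg.n_singlerep_contacts)]
    artifacts = []
    for i in range(cfg.n_artifact_peaks):
        zc, zs, _ze = blacklist[i % len(blacklist)]
        off = 1_000 + (i // len(blacklist)) * 2_000
        artifacts.append((zc, zs + off, zs + off + 500))

    contact_dir = out_dir / "contacts"
    contact_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for r in range(cfg.n_replicates):
        rep = f"rep{r + 1}"
        present = list(all_rep) + list(artifacts)
        if r < 2:
            present += two_rep
        if r == 2:
            present += one_rep
        for fraction in ("odd", "even"):
            rows = [_jitter_peak(rng, *p, cfg.jitter) for p in present]
            for _ in range(cfg.noise_peaks_per_fraction):
                c, s, e = layout.place(int(rng.integers(wlo, whi)))
                rows.append((c, s, e))
            path = contact_dir / f"{rep}_{fraction}.narrowPeak"
            _narrowpeak_frame(rows, f"{rep}_{fraction}").to_csv(
                path, sep="\t", header=False, index=False)
            manifest_rows.append({"replicate": rep, "fraction": fraction, "path": path.name})
        # input control: provenance only; free placement (overlaps are harmless)
        rows = []
        for _ in range(10):
            c = sorted(cfg.chrom_lengths)[int(rng.integers(len(cfg.chrom_lengths)))]
            w = int(rng.integers(wlo, whi))
            s = int(rng.integers(0, cfg.chrom_lengths[c] - w + 1))
            rows.append((c, s, s + w))
        path = contact_dir / f"{rep}_input.narrowPeak"
        _narrowpeak_frame(rows, f"{rep}_input").to_csv(path, sep="\t", header=False, index=False)
        manifest_rows.append({"replicate": rep, "fraction": "input", "path": path.name})
    pd.DataFrame(manifest_rows).to_csv(contact_dir / "manifest.tsv", sep="\t", index=False)

    bl = pd.DataFrame(blacklist, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    bl.to_csv(out_dir / "blacklist.bed", sep="\t", header=False, index=False)

    consensus = sorted(all_rep + two_rep)
    return {
        "consensus_peaks": [[c, int(s), int(e)] for c, s, e in consensus],
        "n_consensus": len(consensus),
        "n_singlerep": len(one_rep),
        "n_artifact": len(artifacts),
        "blacklist_zones": [[c, int(s), int(e)] for c, s, e in blacklist],
    }


def generate_se_atlas(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    layout: _Layout,
    ses: list[_PlantedSE],
    out_dir: Path,
) -> dict:
    """Emit per-sample SE BEDs satisfying the support rules by construction."""
    se_dir = out_dir / "se"
    se_dir.mkdir(parents=True, exist_ok=True)
    cancer_samples = [f"cancer_s{i + 1}" for i in range(3)]
    normal_samples = [f"normal_s{i + 1}" for i in range(6)]
    rows_by_sample: dict[str, list[tuple[str, int, int]]] = {
        s: [] for s in cancer_samples + normal_samples
    }

    def emit(se: _PlantedSE, sample: str, exact: bool) -> None:
        if exact:
            s, e = se.start, se.end
        else:
            j = cfg.se_boundary_jitter
            s = se.start + int(rng.integers(-j, j + 1))
            e = se.end + int(rng.integers(-j, j + 1))
        if not exact and rng.random() < cfg.fragment_prob and (e - s) > cfg.fragment_gap + 2_000:
            mid = (s + e) // 2
            half_gap = cfg.fragment_gap // 2
            rows_by_sample[sample].append((se.chrom, s, mid - half_gap))
            rows_by_sample[sample].append((se.chrom, mid + half_gap, e))
        else:
            rows_by_sample[sample].append((se.chrom, s, e))

    n_five_of_six = 0
    for se in ses:
        exact = se.role == "psi_boundary"  # keep the boundary SE bit-exact
        if se.condition_class in ("cancer-specific", "shared"):
            for sample in cancer_samples:
                emit(se, sample, exact)
        if se.condition_class in ("normal-specific", "shared"):
            chosen = normal_samples if rng.random() < 0.5 else normal_samples[:5]
            if len(chosen) == 5:
                n_five_of_six += 1
            for sample in chosen:
                emit(se, sample, exact=False)
    # sample-private noise SEs: far enough from everything not to gain support
    for sample in cancer_samples + normal_samples:
        for _ in range(cfg.n_noise_ses_per_sample):
            c, s, e = layout.place(8_000, inflate=13_000)
            rows_by_sample[sample].append((c, s, e))

    manifest_rows = []
    for sample, rows in rows_by_sample.items():
        condition = "cancer" if sample.startswith("cancer") else "normal"
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start", "end"]).reset_index(drop=True)
        path = se_dir / f"{sample}.bed"
        df.to_csv(path, sep="\t", header=False, index=False)
        manifest_rows.append({"sample": sample, "condition": condition, "path": path.name})
    pd.DataFrame(manifest_rows).to_csv(se_dir / "manifest.tsv", sep="\t", index=False)

    counts = {"cancer-specific": 0, "normal-specific": 0, "shared": 0}
    for se in ses:
        counts[se.condition_class] += 1
    return {
        "class_counts": counts,
        "n_five_of_six": n_five_of_six,
        "planted_ses": [
            {"key": se.key, "chrom": se.chrom, "start": se.start, "end": se.end,
             "class": se.condition_class, "role": se.role,
             "psi": bool(se.role and se.role.startswith("psi")),
             "marks": [list(m) for m in se.marks]}
            for se in ses
        ],
    }


def generate_correlation_peaks(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    layout: _Layout,
    ses: list[_PlantedSE],
    tss_pairs: list[dict],
    contact_truth: dict,
    out_dir: Path,
) -> dict:
    """Emit the multi-lncRNA correlation-peak table.

    Focal peaks: confirming peaks inside Ψ SEs (on planted contacts), decoys
    inside Ω SEs (off contacts), TSS-mode peaks at planted promoters, and a
    background split into contact-overlapping (confirmed) and isolated
    peaks.  Extra lncRNAs get peaks inside a known number of cancer-specific
    SEs each, for the ranking comparison.
    """
    wlo, whi = cfg.corr_width
    marks_pool = ["H3K4me1", "H3K4me1", "H3K4me1", "H3K4me3", "H3K27ac",
                  "H3K27me3", "H3K36me3", "H3K9me3", "H4K20me1"]
    rows: list[dict] = []
    n_confirmed = 0
    focal_se_keys: set[str] = set()

    def add(chrom, s, e, lnc, mark, sign):
        rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                     "lncrna_id": lnc, "mark": mark, "sign": sign,
                     "rho": round((0.2 + 0.6 * rng.random()) * (1 if sign == "+" else -1), 3)})

    for se in ses:
        for (s, e, mark, sign, confirmed) in se.corr:
            add(se.chrom, s, e, FOCAL_LNC, mark, sign)
            focal_se_keys.add(se.key)
            if confirmed:
                n_confirmed += 1
    for pair in tss_pairs:
        c, s, e, mark, sign = pair["corr"]
        add(c, s, e, FOCAL_LNC, mark, sign)
        n_confirmed += 1

    # background: a subset rides on planted background contact peaks
    bg_contacts = [p for p in contact_truth["consensus_peaks"]]
    rng.shuffle(bg_contacts)
    n_conf_bg = 0
    for c, s, e in bg_contacts:
        if n_conf_bg >= cfg.n_background_confirmed:
            break
        # skip contacts inside SEs or at planted TSSs (those are accounted above)
        if any(se.chrom == c and se.start < e and s < se.end for se in ses):
            continue
        if any(p["contact"][0] == c and p["contact"][1] < e and s < p["contact"][2]
               for p in tss_pairs):
            continue
        w = int(rng.integers(wlo, whi))
        add(c, s, s + w, FOCAL_LNC, marks_pool[int(rng.integers(len(marks_pool)))],
            "+" if rng.random() < 0.75 else "-")
        n_conf_bg += 1
        n_confirmed += 1
    for _ in range(cfg.n_background_corr - n_conf_bg):
        c, s, e = layout.place(int(rng.integers(wlo, whi)))
        add(c, s, e, FOCAL_LNC, marks_pool[int(rng.integers(len(marks_pool)))],
            "+" if rng.random() < 0.75 else "-")

    # extra lncRNAs for the ranking comparison
    cancer_ses = [se for se in ses if se.condition_class == "cancer-specific"]
    lnc_counts: dict[str, int] = {}
    for j in range(cfg.n_extra_lncrnas):
        lnc = f"LNC_{j + 1:03d}"
        count = int(rng.integers(0, cfg.extra_lnc_max_count + 1))
        chosen = rng.choice(len(cancer_ses), size=min(count, len(cancer_ses)), replace=False)
        for idx in chosen:
            se = cancer_ses[int(idx)]
            s = se.start + 5_000 + int(rng.integers(0, max(1, (se.end - se.start) - 6_000)))
            add(se.chrom, s, s + 200, lnc,
                marks_pool[int(rng.integers(len(marks_pool)))],
                "+" if rng.random() < 0.5 else "-")
        lnc_counts[lnc] = int(len(chosen))
    lnc_counts[FOCAL_LNC] = len(focal_se_keys)

    df = pd.DataFrame(rows).sort_values(["chrom", "start", "end", "lncrna_id"]).reset_index(drop=True)
    lio.write_table(df, out_dir / "correlation_peaks.tsv")
    return {
        "n_focal_peaks": int((df["lncrna_id"] == FOCAL_LNC).sum()),
        "n_confirmed": int(n_confirmed),
        "focal_se_count": len(focal_se_keys),
        "lnc_se_counts": lnc_counts,
        "psi_se_keys": sorted(se.key for se in ses if se.role and se.role.startswith("psi")),
    }


def generate_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    layout: _Layout,
    ses: list[_PlantedSE],
    genes: list[dict],
    out_dir: Path,
) -> dict:
    """Emit gene annotation, TPM tables, the cell-line DE table and the cohort.

    Cohort model per gene g and sample s (log2(TPM+1) scale):
    ``x_gs = base_g + shift_g * tumor_s + beta_g * f_s + gamma_g * purity_c_s + eps``
    with ``f`` the latent focal-lncRNA activity and ``purity_c`` the centred
    tumor purity (0 for normal samples).  The focal lncRNA loads on ``f``
    with coefficient 1, so ``beta_g`` controls the planted co-expression.
    """
    # filler genes: background for co-expression draws; not expressed in the
    # cell line (TPM < 1) so they never enter the SE target windows
    fillers = []
    chroms = sorted(cfg.chrom_lengths)
    for i in range(cfg.n_filler_genes):
        # fillers are not expressed in the cell line (TPM < 1), so they can
        # never enter a target window; free placement keeps the layout sparse
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, cfg.chrom_lengths[c] - cfg.gene_width))
        e = s + cfg.gene_width
        fillers.append({
            "gene_id": f"G_BG_{i + 1:03d}", "symbol": f"G_BG_{i + 1:03d}", "chrom": c,
            "start": s, "end": e, "strand": "+" if rng.random() < 0.5 else "-",
            "biotype": "protein_coding", "tpm_cancer": round(float(rng.uniform(0.05, 0.9)), 3),
            "category": "background", "anchor": None, "associated": False,
        })
    normal_anchors = [se for se in ses if se.condition_class == "normal-specific"]
    for i in range(cfg.n_normalblock_genes):
        se = normal_anchors[i % len(normal_anchors)]
        offset = 15_000 + 7_000 * (i // len(normal_anchors))
        fillers.append({
            "gene_id": f"G_NB_{i + 1:03d}", "symbol": f"G_NB_{i + 1:03d}", "chrom": se.chrom,
            "start": se.end + offset, "end": se.end + offset + cfg.gene_width,
            "strand": "+", "biotype": "protein_coding",
            "tpm_cancer": round(float(rng.uniform(2.0, 20.0)), 3),
            "category": "normal_block", "anchor": se.key, "associated": False,
        })
    all_genes = genes + fillers
    # the focal lncRNA gene gets a fixed spot in the chr2 tail, clear of
    # every cancer-specific SE window so it never enters a target list
    focal_row = {
        "gene_id": FOCAL_LNC, "symbol": FOCAL_LNC, "chrom": "chr2",
        "start": 1_980_000, "end": 1_981_000, "strand": "+", "biotype": "lncRNA",
        "tpm_cancer": 120.0, "category": "focal", "anchor": None, "associated": False,
    }
    layout.register("chr2", 1_980_000, 1_981_000)
    table = all_genes + [focal_row]
    _check_planted_design_genes(ses, table)

    # cell-line / normal-tissue TPM replicate tables (means land in genes.tsv)
    gids = [g["gene_id"] for g in table]
    tpm = np.array([g["tpm_cancer"] for g in table])
    cl = pd.DataFrame({"gene_id": gids})
    for r in range(2):
        jit = np.where(tpm == 1.0, 1.0, tpm * (1 + 0.05 * (1 if r == 0 else -1)))
        cl[f"rep{r + 1}"] = np.round(jit, 4)
    nt = pd.DataFrame({"gene_id": gids})
    tpm_normal = np.round(np.asarray(rng.uniform(0.5, 15.0, size=len(gids))), 3)
    for r in range(5):
        nt[f"rep{r + 1}"] = tpm_normal
    expr_dir = out_dir / "expression"
    expr_dir.mkdir(parents=True, exist_ok=True)
    lio.write_table(cl, expr_dir / "cellline_tpm.tsv")
    lio.write_table(nt, expr_dir / "normal_tpm.tsv")

    gene_df = pd.DataFrame(table)
    gene_df["tpm_cancer"] = cl.set_index("gene_id").mean(axis=1).reindex(gene_df["gene_id"]).to_numpy()
    gene_df["tpm_normal"] = tpm_normal
    lio.write_table(
        gene_df[["gene_id", "symbol", "chrom", "start", "end", "strand", "biotype",
                 "tpm_cancer", "tpm_normal"]],
        out_dir / "genes.tsv",
    )

    # cell-line differential expression (Welch on simulated replicates + BH)
    cat = {g["gene_id"]: g["category"] for g in table}
    cl_shift = np.zeros(len(gids))
    for i, gid in enumerate(gids):
        c = cat[gid]
        if c in ("triple", "fail_cohort", "fail_coexpr", "focal"):
            cl_shift[i] = cfg.cellline_lfc
        elif c == "fail_cellline":
            cl_shift[i] = -cfg.cellline_lfc
        elif c == "nonsig":
            cl_shift[i] = 0.03
        elif c == "background" and rng.random() < 0.2:
            cl_shift[i] = float(rng.choice([-1.0, 1.0])) * cfg.cellline_lfc
    base = np.asarray(rng.uniform(3.0, 7.0, size=len(gids)))
    n_r = cfg.n_cellline_reps
    mat = (base[:, None] + cl_shift[:, None] * np.array([1] * n_r + [0] * n_r)[None, :]
           + rng.normal(0, cfg.cellline_sd, size=(len(gids), 2 * n_r)))
    de_expr = pd.DataFrame(mat, index=gids,
                           columns=[f"cl{r}" for r in range(n_r)] + [f"org{r}" for r in range(n_r)])
    from .targets import welch_de
    from .coexpression import bh_adjust

    labels = pd.Series(["tumor"] * n_r + ["normal"] * n_r, index=de_expr.columns)
    de = welch_de(de_expr, labels)
    de["padj"] = bh_adjust(de["p"].to_numpy())
    lio.write_table(de[["gene_id", "log2FC", "p", "padj"]], expr_dir / "de_cellline.tsv")

    # tumor cohort with latent focal activity and a purity confound
    n_t, n_n = cfg.n_tumor, cfg.n_normal_cohort
    samples = [f"T{i + 1:03d}" for i in range(n_t)] + [f"N{i + 1:03d}" for i in range(n_n)]
    is_tumor = np.array([1] * n_t + [0] * n_n)
    purity = np.asarray(rng.uniform(0.25, 0.95, size=n_t))
    purity_c = np.concatenate([purity - purity.mean(), np.zeros(n_n)])
    f = np.asarray(rng.normal(0, 1, size=n_t + n_n))

    beta = np.zeros(len(gids))
    shift = np.zeros(len(gids))
    gamma = np.zeros(len(gids))
    for i, gid in enumerate(gids):
        c = cat[gid]
        if c in ("triple", "fail_cellline"):
            beta[i], shift[i] = cfg.beta_pos, cfg.tumor_shift_up
        elif c == "fail_cohort":
            beta[i], shift[i] = cfg.beta_pos, cfg.tumor_shift_down
        elif c == "fail_coexpr":
            beta[i], shift[i] = cfg.beta_neg, cfg.tumor_shift_up
        elif c == "nonsig":
            beta[i], shift[i] = cfg.beta_pos, cfg.tumor_shift_up
        elif c == "neutral":
            beta[i], shift[i] = cfg.beta_pos, cfg.tumor_shift_up
        elif c in ("background", "normal_block"):
            beta[i] = 0.0
            gamma[i] = cfg.gamma_gene if rng.random() < 0.5 else 0.0
    cohort_base = np.asarray(rng.uniform(3.0, 7.0, size=len(gids)))
    expr = (cohort_base[:, None] + shift[:, None] * is_tumor[None, :]
            + beta[:, None] * f[None, :] + gamma[:, None] * purity_c[None, :]
            + rng.normal(0, cfg.noise_sd, size=(len(gids), n_t + n_n)))
    fidx = gids.index(FOCAL_LNC)
    expr[fidx] = (5.0 + cfg.focal_tumor_shift * is_tumor + 1.0 * f
                  + cfg.gamma_focal * purity_c
                  + rng.normal(0, cfg.focal_noise_sd, size=n_t + n_n))
    expr = np.maximum(expr, 0.0)
    cohort_dir = out_dir / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    mat_df = pd.DataFrame(np.round(expr, 4), index=gids, columns=samples)
    mat_df.index.name = "gene_id"
    mat_df.to_csv(cohort_dir / "expr.tsv", sep="\t")
    purity_out = np.concatenate([purity, np.full(n_n, np.nan)])
    missing_idx = rng.choice(n_t, size=cfg.n_purity_missing, replace=False)
    purity_out[missing_idx] = np.nan
    meta = pd.DataFrame({
        "sample": samples,
        "class": ["tumor"] * n_t + ["normal"] * n_n,
        "purity": np.round(purity_out, 4),
    })
    lio.write_table(meta, cohort_dir / "samples.tsv")

    assoc = [(g["anchor"], g["gene_id"]) for g in genes if g["associated"]]
    triple = sorted(g["gene_id"] for g in genes if g["category"] == "triple" and g["associated"])
    return {
        "n_genes": len(table),
        "associations": sorted(assoc),
        "triple_validated": triple,
        "coexpr_target_genes": sorted(g for _k, g in assoc),
        "gene_categories": cat,
    }


def generate_all(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Emit the full input bundle plus ground_truth.json; returns the truth dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sizes = ChromSizes(cfg.chrom_lengths)
    lio.write_chrom_sizes(sizes, out_dir / "chrom.sizes")
    layout = _Layout(cfg.chrom_lengths, rng)
    ses = _plant_ses(cfg, rng, layout)
    _plant_se_internals(cfg, ses)
    genes = _plant_genes(cfg, ses)
    for g in genes:
        layout.register(g["chrom"], g["start"], g["end"])
    tss_pairs = _plant_tss_corr(cfg, ses, genes)
    for p in tss_pairs:
        layout.register(p["contact"][0], p["contact"][1], p["contact"][2])

    truth: dict = {"seed": cfg.seed, "chrom_sizes": dict(cfg.chrom_lengths)}
    # atlas first: sample-private noise SEs need wide clearance (the 12.5 kb
    # stitch radius), which is easiest to find before the point features land
    truth["se_atlas"] = generate_se_atlas(cfg, rng, layout, ses, out_dir)
    truth["contacts"] = generate_contact_fractions(cfg, rng, layout, ses, tss_pairs, out_dir)
    truth["correlation"] = generate_correlation_peaks(
        cfg, rng, layout, ses, tss_pairs, truth["contacts"], out_dir)
    truth["expression"] = generate_expression(cfg, rng, layout, ses, genes, out_dir)
    truth["tss_mode"] = [
        {"se_key": p["se_key"], "gene_id": p["gene_id"], "mark": p["mark"], "sign": p["sign"]}
        for p in tss_pairs
    ]
    truth["concordant_psi"] = [se.key for se in ses if se.role == "psi_concordant"]
    truth["psi_no_target"] = [se.key for se in ses if se.role == "psi_no_target"]
    truth["psi_nonsig_lead"] = [se.key for se in ses if se.role == "psi_nonsig"]
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def _check_planted_design_genes(ses: list[_PlantedSE], genes: list[dict]) -> None:
    """Defensive invariants: intended target associations are the only ones."""
    cancer = [se for se in ses if se.condition_class == "cancer-specific"]
    for g in genes:
        for se in cancer:
            if se.chrom != g["chrom"]:
                continue
            overlap = g["start"] < se.end and se.start < g["end"]
            dist = 0 if overlap else min(abs(g["start"] - se.end), abs(se.start - g["start"]))
            intended = g["associated"] and g["anchor"] == se.key
            expressed = g["tpm_cancer"] > 1.0
            # consensus boundaries can drift by the per-sample jitter, so
            # unintended genes must clear the window with that slack (the
            # boundary-test SE is emitted without jitter and checked exactly)
            slack = 0 if se.role == "psi_boundary" else 600
            if expressed and not intended and (overlap or dist <= 100_000 + slack):
                raise AssertionError(
                    f"planted gene {g['gene_id']} accidentally associates with {se.key}")
            if intended and not ((overlap or dist <= 100_000 - slack) and expressed):
                raise AssertionError(
                    f"planted gene {g['gene_id']} fails to associate with its anchor {se.key}")


# ---------------------------------------------------------------------------
# focused simulators for calibration / confound experiments
# ---------------------------------------------------------------------------


def simulate_independent_bundle(
    seed: int,
    n_targets: int = 400,
    target_width: int = 2_000,
    n_peaks: int = 150,
    peak_width: int = 1_000,
    n_corr: int = 600,
    corr_width: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    """Targets, peaks and correlation peaks placed mutually independently.

    Under this null both permutation tests should be calibrated: empirical p
    approximately uniform over seeds, fold enrichment near 1.
    """
    sizes = ChromSizes(chrom_lengths or {"chr1": 2_000_000, "chr2": 2_000_000,
                                         "chr3": 2_000_000})
    rng = np.random.default_rng(seed)
    chroms = sorted(sizes)

    def uniform_set(n: int, width: int) -> IntervalSet:
        rows = []
        for _ in range(n):
            c = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, sizes[c] - width + 1))
            rows.append((c, s, s + width))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    from .intervals import shuffle as _shuffle

    # the "observed" peaks are drawn by the same non-overlapping placement
    # the permutation null uses, so under independence observed and null
    # counts are identically distributed
    peaks = _shuffle(uniform_set(n_peaks, peak_width), sizes, rng)
    return {
        "sizes": sizes,
        "targets": uniform_set(n_targets, target_width),
        "peaks": peaks,
        "corr": uniform_set(n_corr, corr_width),
    }


def simulate_purity_confound(
    seed: int,
    n_samples: int = 500,
    n_genes: int = 20,
    beta: float = 0.0,
    gamma_gene: float = 0.8,
    gamma_focal: float = 0.8,
    noise_sd: float = 0.6,
) -> dict:
    """Focal/gene vectors sharing a purity confound, with optional direct coupling.

    With ``beta = 0`` any focal-gene correlation is purely purity-driven and
    the rank-residual partial correlation should vanish; with ``beta != 0``
    and ``gamma = 0`` the Spearman correlation of each gene with the focal
    vector has a closed-form target under the Gaussian copula,
    ``rho_s = (6/pi) * arcsin(rho_pearson / 2)``, returned as
    ``expected_spearman``.
    """
    rng = np.random.default_rng(seed)
    purity = rng.uniform(0.2, 1.0, size=n_samples)
    pc = (purity - purity.mean()) / purity.std()
    f = rng.normal(0, 1, size=n_samples)
    focal = gamma_focal * pc + f * np.sqrt(max(0.0, 1 - gamma_focal**2))
    genes = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        eps = rng.normal(0, noise_sd, size=n_samples)
        genes[i] = beta * f + gamma_gene * pc + eps
    denom = np.sqrt((beta**2 + gamma_gene**2 + noise_sd**2)
                    * (gamma_focal**2 + max(0.0, 1 - gamma_focal**2)))
    rho_pearson = (beta * np.sqrt(max(0.0, 1 - gamma_focal**2))
                   + gamma_gene * gamma_focal) / denom
    expected = (6 / np.pi) * np.arcsin(rho_pearson / 2)
    return {
        "focal": focal,
        "genes": genes,
        "purity": purity,
        "expected_pearson": float(rho_pearson),
        "expected_spearman": float(expected),
    }
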