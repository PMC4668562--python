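"""End-to-end orchestration with seeded reproducibility.

A run executes annotate -> classify -> date -> distribution and,
optionally, the comparative and lineage stages, collecting all summary
statistics into one JSON-serializable report.  Every stochastic stage
draws its seed deterministically from the master seed and the stage
name, so stages can be re-run in isolation and full runs are
reproducible byte for byte (timestamps excluded).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import distribution as dist
from .dating import DEFAULT_RATE, age_distribution, date_elements
from .families import classify_elements, summarize_superfamilies
from .io import read_fasta
from .orthology import (
    call_orthologs,
    compute_pair_divergences,
    divergence_time,
    intra_inter_contrast,
    ng86_ka_ks,
)
from .phylogeny import assign_lineage

GENE_RATE = 6.03e-9  # substitutions per synonymous site per year (Adh calibration)

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth", "stage_seed", "GENE_RATE"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    genome_a: str = ""
    genome_b: str | None = None
    cds_pairs: str | None = None
    marker_map: str | None = None
    out_dir: str = "ltrscape_out"
    seed: int = 0
    rate_ltr: float = DEFAULT_RATE
    rate_gene: float = GENE_RATE
    window_sizes: tuple[int, ...] = (1_000_000, 100_000, 50_000)
    n_sim: int = 10000
    alpha: float = 0.05
    bin_width: float = 0.01
    detection: dict = field(default_factory=dict)
    run_compare: bool = True
    run_lineage: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_sizes" in data:
            data["window_sizes"] = tuple(data["window_sizes"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": 1, "config": asdict(config)}

    genomes_a_list = read_fasta(config.genome_a)
    genomes_a = {g.id: g for g in genomes_a_list}
    params = ann.DetectionParams(**config.detection)

    elements = ann.annotate_genome(genomes_a_list, params)
    families = classify_elements(elements, genomes_a)
    date_elements(elements, genomes_a, r=config.rate_ltr)
    edf = ann.elements_to_dataframe(elements)
    edf.to_csv(out_dir / "elements.tsv", sep="\t", index=False)
    report["annotate"] = {
        "n_elements": len(elements),
        "category_counts": edf.category.value_counts().to_dict(),
    }
    summary = summarize_superfamilies(edf)
    summary.to_csv(out_dir / "superfamily_summary.tsv", sep="\t", index=False)
    report["classify"] = {
        "n_families": len(families),
        "superfamily_summary": summary.to_dict(orient="records"),
    }
    ages = edf.age_years.dropna()
    report["date"] = {
        "n_dated": int(len(ages)),
        "mean_age_my": float(ages.mean() / 1e6) if len(ages) else None,
        "n_age_zero": int((ages == 0).sum()),
        "distribution": age_distribution(ages.tolist()) if len(ages) >= 2 else None,
    }

    report["distribution"] = {}
    mids = {
        sid: grp.loc[grp.category.isin(["IT", "ST"]), ["start", "end"]].mean(axis=1).astype(int).to_numpy()
        for sid, grp in edf.groupby("seq_id")
    }
    seq_lengths = {g.id: g.length for g in genomes_a_list}
    for w in config.window_sizes:
        profiles = dist.window_counts(mids, seq_lengths, w)
        if profiles.empty or profiles.eligible.sum() == 0:
            report["distribution"][str(w)] = {"skipped": "no eligible windows"}
            continue
        if profiles.loc[profiles.eligible, "element_count"].sum() == 0:
            report["distribution"][str(w)] = {"skipped": "no elements in eligible windows"}
            continue
        profiles, rsummary = dist.randomization_test(
            profiles, n_sim=config.n_sim, alpha=config.alpha,
            seed=stage_seed(config.seed, f"randomization_{w}"),
        )
        profiles.to_csv(out_dir / f"windows_{w}.tsv", sep="\t", index=False)
        report["distribution"][str(w)] = rsummary

    if config.marker_map:
        from .io import read_marker_map

        markers = read_marker_map(config.marker_map)
        w = config.window_sizes[0]
        profiles = dist.window_counts(mids, seq_lengths, w)
        rated = dist.marey_rates(markers, profiles)
        rated.to_csv(out_dir / f"gr_rates_{w}.tsv", sep="\t", index=False)
        ok = rated.dropna(subset=["gr_rate"])
        if len(ok) >= 10:
            report["gr_correlation"] = dist.density_correlation(
                ok.element_count.to_numpy(), ok.gr_rate.to_numpy(),
                n_boot=config.n_sim, seed=stage_seed(config.seed, "gr_corr"),
            )

    if config.run_compare and config.genome_b:
        genome_b = read_fasta(config.genome_b)[0]
        calls = call_orthologs(elements, genomes_a, genome_b)
        by_id = {el.element_id: el for el in elements}
        for call in calls:
            compute_pair_divergences(by_id[call.element_id], call, genomes_a, genome_b)
        n_orth = sum(c.status == "orthologous" for c in calls)
        compare: dict = {
            "n_tested": len(calls),
            "n_orthologous": n_orth,
            "n_absent": sum(c.status == "absent" for c in calls),
            "n_ambiguous": sum(c.status == "ambiguous" for c in calls),
        }
        pd.DataFrame([vars(c) for c in calls]).to_csv(
            out_dir / "ortholog_calls.tsv", sep="\t", index=False
        )
        intact_calls = [c for c in calls if not np.isnan(c.K_intra_A)]
        if len(intact_calls) >= 5:
            compare["intra_inter"] = intra_inter_contrast(intact_calls)
            k_inter = [(c.K_inter_5 + c.K_inter_3) / 2 for c in intact_calls]
            if len(k_inter) >= 10:
                est = divergence_time(k_inter, config.rate_ltr, config.bin_width, metric="K")
                compare["divergence_time_ltr"] = asdict(est)
        if config.cds_pairs:
            from .synthetic import read_gene_pairs

            pairs = read_gene_pairs(config.cds_pairs)
            results = [(gid, ng86_ka_ks(a, b)) for gid, a, b in pairs]
            kaks = pd.DataFrame(
                [dict(gene=gid, Ks=r.Ks, Ka=r.Ka, omega=r.omega) for gid, r in results]
            )
            kaks.to_csv(out_dir / "kaks.tsv", sep="\t", index=False)
            compare["kaks"] = {
                "n_pairs": len(kaks),
                "mean_Ks": float(kaks.Ks.mean()),
                "mean_Ka": float(kaks.Ka.mean()),
            }
            if len(kaks) >= 10:
                est = divergence_time(
                    kaks.Ks.tolist(), config.rate_gene, config.bin_width, metric="Ks"
                )
                compare["divergence_time_gene"] = asdict(est)
        report["compare"] = compare

    if config.run_lineage:
        assignments = [assign_lineage(f) for f in families if f.superfamily in ("Copia", "Gypsy")]
        report["lineage"] = {
            "n_assigned": sum(a.lineage != "unassigned" for a in assignments),
            "assignments": [asdict(a) for a in assignments],
        }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# --- evaluation against planted truth -------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """ARI of two partitions of the same items."""
    from scipy.special import comb

    table: dict[tuple, int] = {}
    for la, lb in zip(labels_a, labels_b):
        table[(la, lb)] = table.get((la, lb), 0) + 1
    a_counts: dict = {}
    b_counts: dict = {}
    for (la, lb), c in table.items():
        a_counts[la] = a_counts.get(la, 0) + c
        b_counts[lb] = b_counts.get(lb, 0) + c
    n = len(labels_a)
    sum_comb = sum(comb(c, 2) for c in table.values())
    sum_a = sum(comb(c, 2) for c in a_counts.values())
    sum_b = sum(comb(c, 2) for c in b_counts.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def evaluate_against_truth(
    elements_df: pd.DataFrame,
    manifest: pd.DataFrame,
    min_overlap: float = 0.5,
) -> dict:
    """Score calls against a planted-truth manifest.

    Per category: TP/FP/FN with 50%-reciprocal-overlap matching, plus the
    mean absolute boundary error of matched calls and the adjusted Rand
    index of planted vs inferred family labels over matched elements.
    """
    result: dict = {"categories": {}}
    matched_pairs: list[tuple[pd.Series, pd.Series]] = []
    for cat in ["IT", "InT", "ST", "SnT", "complex"]:
        truth = manifest[manifest.category == cat]
        calls = elements_df[elements_df.category == cat]
        used: set[int] = set()
        tp = 0
        errors: list[float] = []
        for _, t in truth.iterrows():
            best = None
            for ci, c in calls.iterrows():
                if ci in used or c.seq_id != t.seq_id:
                    continue
                ov = _reciprocal_overlap((t.start, t.end), (c.start, c.end))
                if ov >= min_overlap and (best is None or ov > best[0]):
                    best = (ov, ci, c)
            if best is not None:
                used.add(best[1])
                tp += 1
                c = best[2]
                errors.append((abs(c.start - t.start) + abs(c.end - t.end)) / 2)
                matched_pairs.append((t, c))
        fp = len(calls) - tp
        fn = len(truth) - tp
        result["categories"][cat] = {
            "n_truth": int(len(truth)),
            "n_calls": int(len(calls)),
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "boundary_mae_bp": float(np.mean(errors)) if errors else float("nan"),
        }
    if matched_pairs:
        truth_fams = [t.family for t, _ in matched_pairs]
        call_fams = [c.family_id for _, c in matched_pairs]
        result["family_ari"] = adjusted_rand_index(truth_fams, call_fams)
    return result
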