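"""End-to-end audit runs driven by a single configuration mapping.

``run_wgs_audit`` executes normalize -> merge -> confidence filters ->
known-variant exclusion -> specificity classification -> conversion
spectrum -> guide-homology scan; ``run_rna_audit`` adds the region
filter (exonic/intronic/UTR only) and an optional per-position base
fraction table over a target window.  Every run writes its intermediate
tables plus a manifest (config snapshot, input checksums, per-stage
record counts); identical config and inputs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

from . import __version__
from .audit import (
    RNA_CALLER_PRIORITY,
    WGS_CALLER_PRIORITY,
    af_distribution,
    annotate_region,
    apply_confidence_filters,
    classify_tissue_specificity,
    conversion_spectrum,
    exclude_known,
    merge_callers,
    normalize_variant,
    variants_to_table,
)
from .exceptions import ConfigError
from .homology import GuideSpec, scan_variants, summarize_mismatch_profile
from .io_formats import (
    RegionAnnotation,
    load_config,
    read_fasta,
    read_known_sites,
    read_vcf,
)

logger = logging.getLogger("editaudit")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: Mapping, key: str):
    if key not in config:
        raise ConfigError(f"missing configuration field {key!r}")
    return config[key]


def _guide_from_config(config: Mapping) -> GuideSpec:
    g = _require(config, "guide")
    return GuideSpec(
        protospacer=_require(g, "protospacer"),
        pam_pattern=g.get("pam_pattern", "NGG"),
        seed_length=g.get("seed_length", 12),
    )


def _run_audit(config: Mapping, rna_mode: bool) -> dict:
    if isinstance(config, (str, Path)):
        config = load_config(config)
    out_dir = Path(_require(config, "out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    tissues = list(_require(config, "tissues"))
    vcf_map = _require(config, "vcfs")  # caller -> tissue -> path
    default_priority = RNA_CALLER_PRIORITY if rna_mode else WGS_CALLER_PRIORITY
    priority = list(config.get("caller_priority",
                               [c for c in default_priority if c in vcf_map]))
    reference = read_fasta(_require(config, "reference"))
    thresholds = config.get("thresholds", {})

    manifest: dict = {
        "tool": f"editaudit {__version__}",
        "mode": "rna" if rna_mode else "wgs",
        "config": json.loads(json.dumps(config, default=str)),
        "input_checksums": {},
        "stage_counts": {},
    }
    checksums = manifest["input_checksums"]
    checksums[str(config["reference"])] = _sha256(config["reference"])

    callsets = {}
    n_calls = 0
    for caller, per_tissue in vcf_map.items():
        for tissue in tissues:
            path = per_tissue.get(tissue)
            if path is None:
                raise ConfigError(f"no VCF configured for ({caller}, {tissue})")
            calls = read_vcf(path, caller_id=caller)
            callsets[(caller, tissue)] = [normalize_variant(c, reference)
                                          for c in calls]
            checksums[str(path)] = _sha256(path)
            n_calls += len(calls)
    manifest["stage_counts"]["calls_in"] = n_calls

    merged = merge_callers(callsets, priority)
    manifest["stage_counts"]["merged"] = len(merged)

    filtered = apply_confidence_filters(
        merged,
        min_callers=thresholds.get("min_callers", 2),
        min_depth_per_tissue=thresholds.get("min_depth_per_tissue", 5),
        min_alt_total=thresholds.get("min_alt_total", 2),
        unmeasured_depth_passes=thresholds.get("unmeasured_depth_passes", False),
    )
    manifest["stage_counts"]["confidence_filtered"] = len(filtered)

    if rna_mode or "annotation" in config:
        annotation = RegionAnnotation.from_bed(_require(config, "annotation"))
        checksums[str(config["annotation"])] = _sha256(config["annotation"])
        filtered = annotate_region(filtered, annotation, rna_mode=rna_mode)
        manifest["stage_counts"]["region_filtered"] = len(filtered)

    known_sets = []
    for path in config.get("known_sets", []):
        known_sets.append(read_known_sites(path))
        checksums[str(path)] = _sha256(path)
    novel, known = exclude_known(filtered, known_sets)
    manifest["stage_counts"]["novel"] = len(novel)
    manifest["stage_counts"]["known"] = len(known)

    classified = classify_tissue_specificity(filtered, tissues)
    table = variants_to_table(classified, tissues)
    table.to_csv(out_dir / "audited_variants.tsv", sep="\t", index=False)

    specific = [v for v in classified
                if (v.specificity or "").startswith("tissue-specific")]
    common = [v for v in classified if v.specificity == "common"]
    manifest["stage_counts"]["tissue_specific"] = len(specific)
    manifest["stage_counts"]["common"] = len(common)

    spectra = {}
    for label, group in (("tissue_specific", specific), ("common", common)):
        snvs = [v for v in group if v.is_snv]
        spectra[label] = conversion_spectrum(snvs)
    with open(out_dir / "spectrum.tsv", "w") as fh:
        fh.write("group\tclass\tcount\tfraction\n")
        for label, spec in spectra.items():
            fracs = spec.fractions_6()
            for klass, count in spec.counts_6.items():
                fh.write(f"{label}\t{klass}\t{count}\t{fracs[klass]:.6g}\n")

    af_distribution(classified, tissues).to_csv(
        out_dir / "af_distribution.tsv", sep="\t", index=False)

    results = {
        "manifest": manifest, "variants": classified, "novel": novel,
        "tissue_specific": specific, "common": common, "spectra": spectra,
        "out_dir": out_dir,
    }

    if "guide" in config:
        guide = _guide_from_config(config)
        hcfg = config.get("homology", {})
        scan_targets = [v for v in specific if v.is_snv]
        homology = scan_variants(
            scan_targets, reference, guide,
            flank=hcfg.get("flank", 30), mode=hcfg.get("mode", "strict"),
        )
        with open(out_dir / "homology.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tstrand\toffset\tedit_distance\t"
                     "mismatches\tgaps\talignment\n")
            for res in homology:
                k = res.variant_key
                aln = "|".join(res.alignment) if res.alignment else ""
                fh.write(
                    f"{k[0]}\t{k[1]}\t{k[2]}\t{k[3]}\t{res.best_strand}\t"
                    f"{res.best_offset}\t{res.edit_distance}\t{res.mismatches}\t"
                    f"{res.gaps}\t{aln}\n"
                )
        labels = [v.specificity for v in scan_targets]
        summary = summarize_mismatch_profile(homology, labels)
        summary.to_csv(out_dir / "homology_summary.tsv", sep="\t", index=False)
        results["homology"] = homology
        manifest["stage_counts"]["homology_scanned"] = len(homology)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def run_wgs_audit(config: Mapping | str | Path) -> dict:
    """WGS-mode audit: all stages, no region requirement."""
    return _run_audit(config, rna_mode=False)


def run_rna_audit(config: Mapping | str | Path) -> dict:
    """RNA-mode audit: adds the exon/intron/UTR region filter.

    Uses the RNA caller priority by default and requires an annotation
    file; an optional ``reads_table``/``window`` section adds a
    per-position base-fraction table over the target region.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    results = _run_audit(config, rna_mode=True)
    if "reads_table" in config:
        from .amplicon import pileup_and_fractions
        from .io_formats import read_reads_table

        reads = read_reads_table(config["reads_table"])
        window_ref = _require(config, "target_window")
        pileup = pileup_and_fractions(reads, window_ref)
        frac = pileup.fractions()
        out_dir = results["out_dir"]
        with open(out_dir / "position_fractions.tsv", "w") as fh:
            fh.write("position\tref\tA\tC\tG\tT\tdeletion\n")
            for j in range(len(window_ref)):
                vals = "\t".join(f"{frac[i, j]:.6g}" for i in range(5))
                fh.write(f"{j + 1}\t{window_ref[j]}\t{vals}\n")
        results["pileup"] = pileup
    return results


__all__ = ["run_wgs_audit", "run_rna_audit"]
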