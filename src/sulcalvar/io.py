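"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from sulcalvar.sulcal_graph import SulcalGraph
from sulcalvar.variant_scores import VariantRecord

log = logging.getLogger(__name__)


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "participant", "cohort"]
    variants[cols].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for _, row in frame.iterrows():
        records.append(VariantRecord(
            chrom=row["chrom"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"],
            participant=str(row["participant"]), cohort=row["cohort"],
            allele_frequency=(float(row["af"])
                              if "af" in frame.columns
                              and pd.notna(row["af"]) else None),
        ))
    return records


def read_vcf(path, sidecar_tsv) -> list[VariantRecord]:
    """Read variants from a VCF plus a participant/cohort sidecar TSV.

    Only the first 8 VCF columns are used; the sidecar maps
    ``variant_id`` (``chrom:pos:ref:alt``) to ``participant`` and
    ``cohort``.  The gnomAD-style ``AF`` INFO field is read when
    present.
    """
    from cyvcf2 import VCF

    sidecar = pd.read_csv(sidecar_tsv, sep="\t").set_index("variant_id")
    records = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            vid = f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            if vid not in sidecar.index:
                log.warning("VCF variant %s missing from sidecar; skipped",
                            vid)
                continue
            meta = sidecar.loc[vid]
            af = v.INFO.get("AF")
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                participant=str(meta["participant"]),
                cohort=str(meta["cohort"]),
                allele_frequency=float(af) if af is not None else None,
            ))
    return records


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="variant_id")


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="participant")


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="participant")


def write_graphs_json(graphs: dict, path) -> None:
    """Serialize {participant: {(side, region): SulcalGraph}} to JSON."""
    payload = {
        pid: {f"{side}|{region}": g.to_json_dict()
              for (side, region), g in by_region.items()}
        for pid, by_region in graphs.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_graphs_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for pid, by_region in payload.items():
        out[pid] = {}
        for key, gdict in by_region.items():
            side, region = key.split("|", 1)
            out[pid][(side, region)] = SulcalGraph.from_json_dict(gdict)
    return out


def write_bed6(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
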