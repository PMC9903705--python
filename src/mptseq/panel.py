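"""Multi-patient panel pooling and amplicon feasibility filters.

Candidate amplicons (one per somatic variant) pooled across a patient cohort
pass through the commercial design constraints for droplet amplicon panels:
target-region GC in [0.27, 0.70], primer GC in [0.27, 0.62], amplicon length
in [125, 275] bp, no masked/repetitive regions, and pairwise non-overlap.
Variants shared between patients collapse to a single amplicon before
filtering, which is exactly how a multi-patient panel saves target space.
Overlap conflicts keep the higher bulk-VAF variant; a capped panel drops the
lowest-VAF survivors first.  Every rejection records the first failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import AmpliconRecord, VariantRecord


def gc_fraction(seq: str) -> float:
    """GC fraction over non-N bases; errors on empty or all-N sequences."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        raise ValueError("all-N sequence has no defined GC fraction")
    return sum(1 for b in seq if b in "GC") / denom


@dataclass
class PanelRules:
    region_gc: tuple = (0.27, 0.70)
    primer_gc: tuple = (0.27, 0.62)
    amplicon_len: tuple = (125, 275)  # bp; the designed range can be tighter
    forbid_overlap: bool = True
    masked_regions: list = field(default_factory=list)  # (chrom, start, end)
    max_panel_size: int = 380

    def __post_init__(self):
        for name in ("region_gc", "primer_gc", "amplicon_len"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds out of order: {lo} > {hi}")
        if self.max_panel_size < 1:
            raise ValueError("max_panel_size must be >= 1")


@dataclass
class PanelCandidate:
    variant: VariantRecord
    amplicon: AmpliconRecord
    patient: str


def _first_failure(amp: AmpliconRecord, rules: PanelRules) -> str | None:
    """First rule the amplicon violates, in the fixed evaluation order."""
    lo, hi = rules.region_gc
    if pd.notna(amp.gc_fraction) and not lo <= amp.gc_fraction <= hi:
        return "region_gc"
    lo, hi = rules.primer_gc
    if pd.notna(amp.primer_gc) and not lo <= amp.primer_gc <= hi:
        return "primer_gc"
    lo, hi = rules.amplicon_len
    if not lo <= amp.length_bp <= hi:
        return "amplicon_len"
    for chrom, start, end in rules.masked_regions:
        if amp.chrom == chrom and amp.start < end and start < amp.end:
            return "masked_region"
    return None


def design_panel(
    candidates: list, rules: PanelRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool candidates, apply feasibility rules, resolve overlaps, cap size.

    ``candidates`` is a list of :class:`PanelCandidate` (variant + amplicon +
    patient).  Returns ``(panel, report)``: the accepted panel with carrier
    patients per entry, and a rejection report with the first failing rule
    for every deduplicated candidate.  Together they partition the
    deduplicated candidate set.
    """
    rules = rules or PanelRules()
    if not candidates:
        raise ValueError("empty candidate set")

    # collapse identical variants across patients to one amplicon
    pooled: dict = {}
    for cand in candidates:
        key = cand.variant.key
        if key in pooled:
            pooled[key]["patients"].append(cand.patient)
            pooled[key]["bulk_vaf"] = max(
                pooled[key]["bulk_vaf"], cand.variant.bulk_vaf
            )
        else:
            pooled[key] = {
                "key": key,
                "variant": cand.variant,
                "amplicon": cand.amplicon,
                "patients": [cand.patient],
                "bulk_vaf": cand.variant.bulk_vaf,
            }
    entries = list(pooled.values())

    rejected = []
    surviving = []
    for entry in entries:
        reason = _first_failure(entry["amplicon"], rules)
        if reason is None:
            surviving.append(entry)
        else:
            rejected.append((entry, reason))

    # overlap resolution among survivors: keep the higher bulk VAF, then
    # earlier genomic order
    if rules.forbid_overlap:
        order = sorted(
            surviving,
            key=lambda e: (
                -(e["bulk_vaf"] if pd.notna(e["bulk_vaf"]) else -1.0),
                e["amplicon"].chrom,
                e["amplicon"].start,
            ),
        )
        kept: list = []
        for entry in order:
            amp = entry["amplicon"]
            clash = any(
                amp.chrom == other["amplicon"].chrom
                and amp.start < other["amplicon"].end
                and other["amplicon"].start < amp.end
                for other in kept
            )
            if clash:
                rejected.append((entry, "overlap"))
            else:
                kept.append(entry)
        surviving = kept

    # panel size cap: drop lowest VAF first
    if len(surviving) > rules.max_panel_size:
        surviving = sorted(
            surviving,
            key=lambda e: (
                -(e["bulk_vaf"] if pd.notna(e["bulk_vaf"]) else -1.0),
                e["amplicon"].chrom,
                e["amplicon"].start,
            ),
        )
        for entry in surviving[rules.max_panel_size:]:
            rejected.append((entry, "max_panel_size"))
        surviving = surviving[: rules.max_panel_size]

    def row(entry, status, reason=""):
        var, amp = entry["variant"], entry["amplicon"]
        return {
            "amplicon_id": amp.amplicon_id,
            "chrom": amp.chrom, "start": amp.start, "end": amp.end,
            "length_bp": amp.length_bp, "gc_fraction": amp.gc_fraction,
            "primer_gc": amp.primer_gc,
            "variant": f"{var.chrom}:{var.pos}:{var.ref}>{var.alt}",
            "gene": var.gene, "bulk_vaf": entry["bulk_vaf"],
            "patients": ",".join(sorted(set(entry["patients"]))),
            "status": status, "reason": reason,
        }

    genomic = lambda e: (e["amplicon"].chrom, e["amplicon"].start)
    panel = pd.DataFrame([row(e, "accepted") for e in sorted(surviving, key=genomic)])
    report_rows = [row(e, "rejected", reason) for e, reason in rejected]
    report = pd.DataFrame(
        report_rows,
        columns=list(panel.columns) if len(panel) else None,
    )
    return panel, report


def retention_by_patient(panel: pd.DataFrame, report: pd.DataFrame) -> pd.Series:
    """Fraction of each patient's candidates that made it onto the panel."""
    def explode(frame, accepted):
        if not len(frame):
            return pd.DataFrame(columns=["patient", "accepted"])
        out = frame.assign(patient=frame["patients"].str.split(",")).explode("patient")
        return out.assign(accepted=accepted)[["patient", "accepted"]]

    both = pd.concat([explode(panel, True), explode(report, False)])
    return both.groupby("patient")["accepted"].mean().rename("retention")
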