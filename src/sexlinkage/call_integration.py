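"""Merging of per-approach evidence into species-level sex-chromosome calls.

Three detection routes feed in: A1, the tribe-wise per-SNP sex-association
scan; A2, the tribe-wise sex-specific-SNP accumulation scan; A3, the
species-level transcriptome allele-count scan. The merged calls come in two
flavors: a *permissive* set keeping every call, and a *stringent* set
excluding calls (and linkage groups within multi-LG calls) supported only by
A2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_prep import SexlinkageError

EVIDENCE_CODES = ("A1", "A2", "A3", "literature")


@dataclass
class SpeciesCall:
    """A per-species sex-chromosome call with provenance."""

    species_id: str
    lg_ids: frozenset  # >= 1 entries; multi-LG allowed (fusion signals)
    system: str  # "XY" or "ZW"
    evidence: frozenset  # subset of EVIDENCE_CODES, per call
    lg_evidence: dict = field(default_factory=dict)  # lg_id -> evidence set
    notes: list = field(default_factory=list)

    def __post_init__(self):
        self.lg_ids = frozenset(self.lg_ids)
        self.evidence = frozenset(self.evidence)
        if not self.evidence:
            raise SexlinkageError("evidence must be nonempty")
        if self.system not in ("XY", "ZW"):
            raise SexlinkageError(f"invalid system {self.system!r}")
        if not self.lg_evidence:
            self.lg_evidence = {lg: set(self.evidence) for lg in self.lg_ids}


@dataclass
class CallSet:
    flavor: str  # "permissive" or "stringent"
    calls: list
    no_signal_species: list = field(default_factory=list)

    def species(self) -> set:
        return {c.species_id for c in self.calls}


def integrate_calls(
    a1: list, a2: list, a3: list, literature: list | None = None,
    all_species: list | None = None,
) -> tuple[CallSet, CallSet]:
    """Merge approach-level calls into permissive and stringent call sets.

    Same species, same LG: evidence merged. Same species, different LGs with
    the same heterogamety: treated as a fusion-compatible multi-LG call, all
    LGs kept with per-LG evidence. Contradictory heterogamety between
    approaches: the call is flagged in the permissive set (resolving toward
    the A3-supported system when one side has A3) and dropped from the
    stringent set. Stringent additionally removes calls supported only by A2
    and prunes A2-only LGs from multi-LG calls.
    """
    tagged = (
        [(c, "A1") for c in a1]
        + [(c, "A2") for c in a2]
        + [(c, "A3") for c in a3]
        + [(c, "literature") for c in (literature or [])]
    )
    by_species: dict[str, list[SpeciesCall]] = {}
    for call, _tag in tagged:
        by_species.setdefault(call.species_id, []).append(call)

    permissive: list[SpeciesCall] = []
    conflicted: set[str] = set()
    for sp, calls in sorted(by_species.items()):
        systems = {c.system for c in calls}
        notes = []
        if len(systems) > 1:
            conflicted.add(sp)
            with_a3 = [c for c in calls if "A3" in c.evidence]
            if with_a3:
                system = with_a3[0].system
                notes.append(
                    f"heterogamety conflict {sorted(systems)}; resolved to "
                    f"A3-supported {system}"
                )
                calls = [c for c in calls if c.system == system]
            else:
                system = sorted(systems)[0]
                notes.append(f"heterogamety conflict {sorted(systems)}; unresolved")
                calls = [c for c in calls if c.system == system]
        else:
            system = calls[0].system
        lg_evidence: dict[str, set] = {}
        evidence: set = set()
        for c in calls:
            evidence |= set(c.evidence)
            for lg in c.lg_ids:
                lg_evidence.setdefault(lg, set()).update(c.lg_evidence.get(lg, c.evidence))
            notes.extend(c.notes)
        permissive.append(
            SpeciesCall(sp, frozenset(lg_evidence), system, frozenset(evidence),
                        {k: set(v) for k, v in lg_evidence.items()}, notes)
        )

    stringent: list[SpeciesCall] = []
    for c in permissive:
        if c.species_id in conflicted:
            continue
        if c.evidence == frozenset({"A2"}):
            continue
        kept = {lg: ev for lg, ev in c.lg_evidence.items() if ev != {"A2"}}
        if not kept:
            continue
        stringent.append(
            SpeciesCall(c.species_id, frozenset(kept), c.system, c.evidence,
                        {k: set(v) for k, v in kept.items()}, list(c.notes))
        )

    called = {c.species_id for c in permissive}
    no_signal = sorted(set(all_species or []) - called)
    return (
        CallSet("permissive", permissive, no_signal),
        CallSet("stringent", stringent,
                sorted(set(all_species or []) - {c.species_id for c in stringent})),
    )


def summarize_calls(cs: CallSet) -> dict:
    """Heterogamety and recruitment summary of a call set.

    ``pct_xy`` is the percentage of called species with an XY system, rounded
    to one decimal; per-LG recruitment counts each species once per LG it
    recruited.
    """
    n_xy = sum(1 for c in cs.calls if c.system == "XY")
    n_zw = sum(1 for c in cs.calls if c.system == "ZW")
    total = n_xy + n_zw
    per_lg: dict[str, int] = {}
    for c in cs.calls:
        for lg in sorted(c.lg_ids):
            per_lg[lg] = per_lg.get(lg, 0) + 1
    return {
        "flavor": cs.flavor,
        "n_called": total,
        "n_xy": n_xy,
        "n_zw": n_zw,
        "pct_xy": round(100.0 * n_xy / total, 1) if total else 0.0,
        "pct_zw": round(100.0 * n_zw / total, 1) if total else 0.0,
        "per_lg_counts": dict(sorted(per_lg.items())),
        "n_no_signal": len(cs.no_signal_species),
    }


def calls_to_frame(cs: CallSet) -> pd.DataFrame:
    rows = [
        {
            "species_id": c.species_id,
            "lg_ids": ";".join(sorted(c.lg_ids)),
            "system": c.system,
            "evidence": ";".join(sorted(c.evidence)),
            "flavor": cs.flavor,
            "notes": " | ".join(c.notes),
        }
        for c in cs.calls
    ]
    return pd.DataFrame(
        rows, columns=["species_id", "lg_ids", "system", "evidence", "flavor", "notes"]
    )
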