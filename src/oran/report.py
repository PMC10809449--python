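"""Run-report bookkeeping shared by the CLI subcommands."""

from __future__ import annotations


def summarize_antigen_counts(per_category: dict[str, int]) -> dict[str, int]:
    """Total an antigen report across categories.

    ``per_category`` maps category name (e.g. "neoantigen", "TAA") to
    its count; the returned summary repeats the categories and adds a
    ``"total"`` key. Negative counts are rejected.
    """
    if any(v < 0 for v in per_category.values()):
        raise ValueError("antigen counts cannot be negative")
    out = dict(per_category)
    out["total"] = sum(per_category.values())
    return out
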