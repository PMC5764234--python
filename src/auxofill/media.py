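"""Media and experiment-condition vocabulary shared across modules.

Experiments are rows of a metadata table with columns ``exp_id``,
``media_class`` ({rich, defined}), ``supplements`` (";"-separated
``compound:mM`` pairs, possibly empty), ``carbon_source``,
``nitrogen_source``, ``replicate_group``, ``time0_id`` and ``generations``.

Amino acids are named by lower-case three-letter codes.  Complex
amino-acid supplements (casamino acids, yeast extract) make a defined
medium amino-acid replete for phenotype purposes; casamino acids lacks
tryptophan, which callers may choose to honor.
"""

from __future__ import annotations

AMINO_ACIDS = [
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
]

#: complex supplements that supply (nearly) all amino acids
REPLETE_SUPPLEMENTS = {"casamino_acids", "yeast_extract"}

#: amino acids missing from each complex supplement
REPLETE_GAPS = {"casamino_acids": {"trp"}, "yeast_extract": set()}


def parse_supplements(spec: str) -> dict[str, float]:
    """Parse ``"his:1;met:10"`` into ``{"his": 1.0, "met": 10.0}``."""
    if spec is None or (isinstance(spec, float)) or not str(spec).strip():
        return {}
    out: dict[str, float] = {}
    for item in str(spec).split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" in item:
            name, conc = item.rsplit(":", 1)
            out[name.strip()] = float(conc)
        else:
            out[item] = float("nan")
    return out


def format_supplements(supps: dict[str, float]) -> str:
    return ";".join(f"{k}:{v:g}" for k, v in supps.items())


def is_replete(exp) -> bool:
    """True if the experiment's medium supplies most amino acids."""
    if exp["media_class"] == "rich":
        return True
    return bool(REPLETE_SUPPLEMENTS & set(parse_supplements(exp.get("supplements", ""))))


def supplemented_amino_acids(exp, expand_complex: bool = False) -> set[str]:
    """Amino acids individually supplied to a defined-medium experiment.

    With ``expand_complex`` the amino acids contributed by casamino acids /
    yeast extract are included too (minus tryptophan for casamino acids).
    """
    supps = set(parse_supplements(exp.get("supplements", "")))
    aas = supps & set(AMINO_ACIDS)
    if expand_complex:
        for name in supps & REPLETE_SUPPLEMENTS:
            aas |= set(AMINO_ACIDS) - REPLETE_GAPS[name]
    return aas


def is_defined_minimal(exp) -> bool:
    """A defined-medium experiment with no amino-acid supplement of any kind."""
    if exp["media_class"] != "defined":
        return False
    return not is_replete(exp) and not supplemented_amino_acids(exp)
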