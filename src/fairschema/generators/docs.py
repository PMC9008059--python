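"""Human-readable documentation: Markdown overview and LaTeX article.

The Markdown output (CommonMark with pipe tables) opens with the schema's
summary statistics, then renders one section per module with one table row
per element, hyperlinking ontology annotations to their IRIs and lookup
elements to their TSV files. Lookup lists are always linked rather than
inlined, so very large vocabularies never bloat the document.

The LaTeX output is a plain ``article`` with UTF-8 input encoding and no
other package dependencies, one table/tabular per module, compilable with
a stock latex -> dvips -> ps2pdf chain.
"""

from __future__ import annotations

import re

from fairschema.generators.base import Generator, register
from fairschema.io import lookup_filename
from fairschema.model import SemanticSchema, compute_statistics

__all__ = ["generate_markdown", "generate_latex", "MarkdownGenerator", "LatexGenerator"]


def _anchor(name: str) -> str:
    """GitHub-style heading anchor."""
    return re.sub(r"[^0-9a-z-]", "", name.lower().replace(" ", "-"))


def generate_markdown(schema: SemanticSchema) -> str:
    stats = compute_statistics(schema)
    lines: list[str] = []
    lines.append(f"# {schema.name} v{schema.version}")
    lines.append("")
    lines.append(schema.description)
    lines.append("")
    lines.append(f"License: {schema.license}. Released {schema.date}.")
    lines.append("")
    lines.append("## Summary statistics")
    lines.append("")
    lines.append(f"- Modules: {stats.n_modules}")
    lines.append(f"- Elements: {stats.n_elements}")
    lines.append(f"- Elements with lookup values: {stats.n_lookup_elements}")
    lines.append(f"- Unique lookup lists: {stats.n_unique_lookup_lists}")
    lines.append(
        f"- Lookup options across all elements: {stats.total_lookup_options_per_element_sum}"
    )
    lines.append(f"- Unique lookup options: {stats.total_unique_lookup_options}")
    if stats.min_list:
        lines.append(f"- Smallest lookup list: {stats.min_list[0]} ({stats.min_list[1]})")
        lines.append(f"- Largest lookup list: {stats.max_list[0]} ({stats.max_list[1]})")
    lines.append(f"- Newly minted terms: {stats.n_new_terms}")
    lines.append("")
    lines.append("## Modules")
    lines.append("")
    for module in schema.modules:
        lines.append(f"- [{module.name}](#{_anchor(module.name)})")
    lines.append("")
    for module in schema.modules:
        ann = module.annotation
        lines.append(f"## {module.name}")
        lines.append("")
        lines.append(f"{module.description} Defined by [{ann.codesystem} {ann.code}]({ann.iri}).")
        lines.append("")
        lines.append("| Element | Type | Description | Ontology | Lookup |")
        lines.append("| --- | --- | --- | --- | --- |")
        for el in module.elements:
            a = el.annotation
            if el.lookup_ref:
                lookup = f"[{el.lookup_ref}](lookups/{lookup_filename(el.lookup_ref)})"
            elif el.reference_target:
                lookup = f"[{el.reference_target}](#{_anchor(el.reference_target)})"
            else:
                lookup = ""
            lines.append(
                f"| {el.name} | {el.value_type.value} | {el.description} "
                f"| [{a.codesystem} {a.code}]({a.iri}) | {lookup} |"
            )
        lines.append("")
    return "\n".join(lines)


_LATEX_ESCAPES = {
    "\\": r"\textbackslash{}",
    "#": r"\#",
    "$": r"\$",
    "%": r"\%",
    "&": r"\&",
    "_": r"\_",
    "{": r"\{",
    "}": r"\}",
    "~": r"\textasciitilde{}",
    "^": r"\textasciicircum{}",
}


def latex_escape(text: str) -> str:
    return "".join(_LATEX_ESCAPES.get(c, c) for c in text)


def generate_latex(schema: SemanticSchema) -> str:
    e = latex_escape
    lines = [
        r"\documentclass{article}",
        r"\usepackage[utf8]{inputenc}",
        r"\begin{document}",
        rf"\title{{{e(schema.name)} v{e(schema.version)}}}",
        rf"\author{{{e('; '.join(schema.authors))}}}",
        rf"\date{{{e(schema.date)}}}",
        r"\maketitle",
        "",
        e(schema.description),
        "",
    ]
    for module in schema.modules:
        lines += [
            r"\begin{table}[h!]",
            rf"\caption{{{e(module.name)}: {e(module.description)}}}",
            r"\begin{tabular}{lll}",
            r"Element & Type & Ontology \\",
            r"\hline",
        ]
        for el in module.elements:
            lines.append(
                rf"{e(el.name)} & {e(el.value_type.value)} & "
                rf"{e(el.annotation.codesystem)} {e(el.annotation.code)} \\"
            )
        lines += [r"\end{tabular}", r"\end{table}", ""]
    lines.append(r"\end{document}")
    return "\n".join(lines) + "\n"


@register
class MarkdownGenerator(Generator):
    target_name = "markdown"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return [("index.md", generate_markdown(schema).encode("utf-8"))]


@register
class LatexGenerator(Generator):
    target_name = "latex"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return [("schema.tex", generate_latex(schema).encode("utf-8"))]
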