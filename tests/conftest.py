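import pytest

from hvfkit import builtin_layouts, random_report
from hvfkit.glyphs import TemplateSet

PATTERNS = ("24-2", "30-2", "10-2")
SEVERITIES = ("MILD", "MODERATE", "SEVERE")


def make_report(i: int, seed_base: int = 0, **overrides):
    """Seeded report with study-like variety across patterns/eyes/severity."""
    kwargs = dict(
        seed=seed_base + i,
        pattern=PATTERNS[i % 3],
        laterality="OD" if i % 2 == 0 else "OS",
        severity=SEVERITIES[i % 3],
    )
    kwargs.update(overrides)
    return random_report(**kwargs)


@pytest.fixture(scope="session")
def layouts():
    return builtin_layouts()


@pytest.fixture(scope="session")
def canonical_templates(layouts):
    return {
        v: TemplateSet.canonical(v, spec.glyph_scale)
        for v, spec in layouts.items()
    }
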