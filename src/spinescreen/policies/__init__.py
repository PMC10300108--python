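"""Reference screening policies shipped with the package.

* ``agile_worked_example.xml`` — the crisp tolerance-check policy for
  torso-Z sit-to-stand screening: amplitude dead-zone 2 ± 0.5, then
  width dead-zone 100 ± 10 samples; decisions SpineOK / SpineNOK.
* ``fuzzy_reference.xml`` — the Mamdani policy with Small/Medium/High
  trapezoids over Amplitude ∈ [0, 4], Width ∈ [0, 400] samples and
  severity ∈ [0, 1], and the monotone 3×3 rule base.  The membership
  parameters are this package's calibration of the screening fixture,
  not measured constants.
"""

from importlib.resources import files

from ..fuzzy_engine import FuzzyPolicy, parse_fuzzy_policy
from ..pdl_model import PolicySuite, parse_policy_suite

__all__ = [
    "agile_worked_example_xml",
    "fuzzy_reference_xml",
    "agile_worked_example_path",
    "fuzzy_reference_path",
    "load_agile_worked_example",
    "load_fuzzy_reference",
]


def _read(name: str) -> str:
    return (files(__package__) / name).read_text(encoding="utf-8")


def agile_worked_example_path():
    return files(__package__) / "agile_worked_example.xml"


def fuzzy_reference_path():
    return files(__package__) / "fuzzy_reference.xml"


def agile_worked_example_xml() -> str:
    return _read("agile_worked_example.xml")


def fuzzy_reference_xml() -> str:
    return _read("fuzzy_reference.xml")


def load_agile_worked_example() -> PolicySuite:
    return parse_policy_suite(agile_worked_example_xml())


def load_fuzzy_reference() -> FuzzyPolicy:
    return parse_fuzzy_policy(fuzzy_reference_xml())
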