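"""Screen a single answer sheet through both fuzzy channels.

Builds one maximally symptomatic subject, ranks the PCOS levels (P1 high /
P2 normal / P3 moderate) and mental-health levels (M1/M2/M3) by fuzzy
TOPSIS closeness coefficient, and fuses the two selected levels through
the clinician rule base.
"""

from pcoscreen import Instrument, SubjectResponse, screen_subject

instrument = Instrument.default()
subject = SubjectResponse(
    "demo", {c.id: c.levels[-1] for c in instrument.criteria}
)

result = screen_subject(subject)
print("PCOS channel CCs:        ",
      {a: round(cc, 3) for a, cc in result.cc_physical.items()})
print("mental-health channel CCs:",
      {a: round(cc, 3) for a, cc in result.cc_mental.items()})
print(f"selected levels: {result.p_level}, {result.m_level}"
      f"  ->  category {result.category}")
# A closeness coefficient near 1 means the level sits close to the fuzzy
# positive ideal; the top-ranked pair (P1, M1) fuses to A1 = both PCOS and
# mental-health issues.
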