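# Default cue-phrase ruleset: category code -> list of phrase patterns.
# Patterns are matched case-insensitively as whole-word-bounded contiguous
# phrases inside the normalised heading; each word tolerates a plural -s.
# A heading matching several categories is assigned to all of them; a
# heading matching none falls back to OTHER (which may never carry rules).
INTRO:
  - introduction
  - background
CONCL:
  - conclusion
  - key message
  - future
  - summary
  - recommendation
  - implications for clinical practice
  - concluding remark
METHODS:
  - method
  - methodology
  - experimental procedure
  - experimental design
  - experimental section
  - study design
  - study population
  - statistical analysis
RESULTS:
  - result
  - finding
DISCUSSION:
  - discussion
CASE:
  - case study
  - case report
  - case presentation
  - case description
ACK:
  - acknowledgement
  - acknowledgment
  - funding
  - financial support
  - grant support
AUTH_CON:
  - author contribution
  - authorship
  - contribution of author
COMP_INT:
  - competing interest
  - conflict of interest
  - declaration of interest
  - disclosure
SUPPL:
  - supplementary material
  - supplementary data
  - supplementary information
  - supplemental material
  - supplemental data
  - supporting information
  - additional file
ABBR:
  - abbreviation
  - acronym
  - list of abbreviation
KEYWORDS:
  - keyword
  - key word
  - index term
REF:
  - reference
  - literature cited
  - bibliography
  - works cited
FIG:
  - figure
  - fig
  - figure legend
TABLE:
  - table
APPENDIX:
  - appendix
  - appendices
  - annex
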