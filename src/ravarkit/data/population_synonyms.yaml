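# Synonym table mapping reported sample-ethnicity labels to the nine canonical
# geographical populations. Keys are canonical PopulationLabel values; entries
# are matched case-insensitively with whitespace/hyphen/underscore folding.
# Extend locally by adding synonyms; a label absent here is a hard error.
European:
  - European
  - European American
  - European Australian
  - European New Zealander
  - West European
  - North European
  - South European
  - East European
EastAsian:
  - East Asian
  - South East Asian
  - SouthEast Asian
WestAsian:
  - West Asian
SouthAsian:
  - South Asian
SouthAmerican:
  - South American
CentralAmerican:
  - Central American
NorthAfrican:
  - North African
SouthAfrican:
  - South African
AfricanAmerican:
  - African American
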