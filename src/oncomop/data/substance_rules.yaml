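# Ordered regular-expression rules applied to raw substance free text
# before splitting into individual names.  Patterns run top to bottom;
# each is substituted with its replacement everywhere it matches.
# Registries can override this file to match their local reporting
# idiosyncrasies; splitting, lowercasing and whitespace collapsing
# happen after the rules and are not configurable here.
rules:
  # parenthetical qualifiers: "(weekly)", "(liposomal)" ...
  - pattern: '\([^)]*\)'
    replacement: ' '
  # dosage with unit, optionally per body measure: "75mg/m2", "2 g", "500 mg / m²"
  - pattern: '(?i)\b\d+(?:[.,]\d+)?\s*(?:mg|g|mcg|µg|ug|ml|ie|i\.e\.|e)\b(?:\s*/\s*(?:m2|m²|kg|kgkg|d|die|tag|woche))?'
    replacement: ' '
  # AUC dosing of platinum drugs: "AUC5", "AUC 6"
  - pattern: '(?i)\bauc\s*\d+(?:[.,]\d+)?'
    replacement: ' '
  # trade-name punctuation and symbols
  - pattern: '[®™©]'
    replacement: ' '
  # administration-schedule tokens: "d1-3", "q3w", "1x", "3x weekly"
  - pattern: '(?i)\b(?:d\d+(?:-\d+)?|q\d+w|\d+x)\b'
    replacement: ' '
  # stray bare numbers left over after unit stripping; numbers glued to
  # a hyphen stay ("5-fluorouracil")
  - pattern: '(?<![\w-])\d+(?:[.,]\d+)?(?![\w-])'
    replacement: ' '
  # percent signs orphaned by number stripping
  - pattern: '%'
    replacement: ' '
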