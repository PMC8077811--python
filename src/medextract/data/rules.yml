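# Default French attribute rule set.
#
# Patterns are regular expressions over *normalized* text (accents stripped,
# decimals as commas, apostrophes as spaces). Rules are applied in file order
# within a window around each dictionary anchor; earlier rules take priority
# when matches overlap (attribute priority: dosage > frequency > duration >
# route > condition). Unless case_sensitive is set, matching folds case.
rules:
  # ---- dosage ----
  - attribute: dosage
    pattern: '\b\d+(?:,\d+)?\s*(?:mg|g|ml|ui|cp|comprimes?|gelules?|gouttes?|sachets?|bouffees?)\b'
  # ---- frequency ----
  - attribute: frequency
    pattern: '\b\d+\s*fois par (?:jour|semaine|mois)\b'
  - attribute: frequency
    pattern: '\btoutes les \d+\s*(?:heures|h)\b'
  - attribute: frequency
    pattern: '\b(?:le\s+)?(?:matin|midi|soir)(?:(?:\s*,\s*|\s+et\s+|\s+)(?:le\s+)?(?:matin|midi|soir))*\b'
  - attribute: frequency
    pattern: '\bau coucher\b'
  # ---- duration ----
  - attribute: duration
    pattern: '\bpendant \d+\s*(?:jours?|semaines?|mois)\b'
  - attribute: duration
    pattern: '\bjusqu a la prochaine consultation\b'
  # ---- route ----
  - attribute: route
    pattern: '\bper os\b'
  - attribute: route
    pattern: '\bvoie (?:orale|intraveineuse|intramusculaire|sous cutanee)\b'
  - attribute: route
    pattern: '\b(?:IV|IM|SC)\b'
    case_sensitive: true
  # ---- condition ----
  - attribute: condition
    pattern: '\bsi (?:douleurs?|fievre|besoin|nausees|insomnie|toux|crise)\b'
  - attribute: condition
    pattern: '\ben cas de (?:douleurs?|fievre|crise|nausees|vomissements|malaise)\b'
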