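# Spoken-form to symbol mapping applied during transcript normalisation.
# Editable: recognizer backends with different spelling conventions can
# extend these tables. Keys are upper-cased whole tokens.
letters:
  AY: A
  BEE: B
  CEE: C
  SEE: C
  DEE: D
  EE: E
  EF: F
  GEE: G
  AITCH: H
  HAITCH: H
  JAY: J
  KAY: K
  EL: L
  ELL: L
  EM: M
  EN: N
  PEE: P
  CUE: Q
  QUEUE: Q
  AR: R
  ARE: R
  ES: S
  ESS: S
  TEE: T
  YOU: U
  VEE: V
  EX: X
  WHY: Y
  ZEE: Z
  ZED: Z
numbers:
  ZERO: "0"
  OH: "0"
  O: "0"
  ONE: "1"
  TWO: "2"
  TOO: "2"
  THREE: "3"
  FOUR: "4"
  FOR: "4"
  FIVE: "5"
  SIX: "6"
  SEVEN: "7"
  EIGHT: "8"
  ATE: "8"
  NINE: "9"
commands:
  BLUR: BLURRED
  BLURRY: BLURRED
  OKAY: OK
  AGAIN: REPEAT
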