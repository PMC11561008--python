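# Decision-tree adjacency for menstrual cycle status classification.
#
# The adjacency is data, not code, so alternative question orders can be
# loaded and tested without touching the walker.  Each internal node has a
# binary question; "yes"/"no" name the child node, a leaf code, or the
# "natural" subtree link.  The natural-cycle question order is a
# reconstruction consistent with every printed leaf criterion; the source
# figures are images, so the exact original wording/order is not
# machine-readable.
basic:
  root: q_menarche
  nodes:
    q_menarche:
      question: "Has menarche (the first menstrual bleed) occurred?"
      "yes": q_contraception
      "no": q_age
    q_age:
      question: >-
        Is the individual 15 years or older (or 14 or older with no
        secondary sex characteristics present)?
      "yes": A2
      "no": A1
    q_contraception:
      question: >-
        Is hormonal contraception (anything other than a copper IUD)
        currently in use?
      "yes": HC
      "no": q_recent_bleed
    q_recent_bleed:
      question: "Has a menstrual bleed occurred within the last 3 months?"
      "yes": natural
      "no": FHA
natural:
  root: q_prolonged
  nodes:
    q_prolonged:
      question: >-
        Is the cycle longer than 35 days, or have there been 9 or fewer
        menstrual bleeds in the last fully observed year?
      "yes": F
      "no": q_short
    q_short:
      question: "Is the cycle shorter than 21 days?"
      "yes": D2
      "no": q_lh_done
    q_lh_done:
      question: >-
        Were urinary LH (ovulation) tests completed this cycle, and is that
        evidence readable at the agreed monitoring tier?
      "yes": q_lh_pos
      "no": B1
    q_lh_pos:
      question: "Was any urinary LH test positive (LH surge detected)?"
      "yes": q_luteal
      "no": E
    q_luteal:
      question: >-
        Did the next menstrual bleed begin fewer than 14 days after the
        positive LH test?
      "yes": D2
      "no": q_p4_done
    q_p4_done:
      question: >-
        Was a mid-luteal progesterone blood test completed 7-9 days after
        the positive LH test, and is it readable at the agreed tier?
      "yes": q_p4_high
      "no": B1_PROBABLE_OV
    q_p4_high:
      question: "Is the mid-luteal blood progesterone above 16 nmol/L?"
      "yes": C1
      "no": D1
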