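{
  "social": [
    "friend*", "buddy", "buddies", "pal", "pals", "people", "person",
    "everyone", "someone", "anybody", "together", "party", "parties",
    "talk*", "chat*", "call*", "text*", "meet*", "hang*", "date", "dates",
    "dating", "boyfriend*", "girlfriend*", "partner*", "family", "brother*",
    "sister*", "mom", "dad", "roommate*", "neighbor*", "crowd", "group*",
    "social", "visit*", "invite*", "guest*", "crew"
  ],
  "affect": [
    "love*", "like", "likes", "liked", "happy", "happi*", "glad", "joy*",
    "excit*", "amaz*", "awesome", "great", "good", "nice", "fun", "funny",
    "lol", "haha*", "sweet", "sad", "cry*", "hurt*", "hate*", "angry",
    "anger*", "mad", "upset*", "worr*", "fear*", "scare*", "anxi*",
    "stress*", "lonely", "miss*", "sorry", "beautiful", "ugly", "terrible",
    "awful", "annoy*", "proud", "shame*"
  ],
  "drives": [
    "work*", "goal*", "win*", "won", "success*", "achiev*", "try", "tries",
    "tried", "trying", "earn*", "money", "pay*", "paid", "job*", "career*",
    "boss", "power*", "lead*", "control*", "plan*", "push*", "drive*",
    "motivat*", "ambiti*", "compet*", "best", "better", "improve*",
    "effort*", "deadline*", "hustle"
  ],
  "cognitive_processes": [
    "think*", "thought*", "know*", "knew", "because", "cause", "reason*",
    "why", "how", "understand*", "realize*", "remember*", "forget*",
    "forgot", "believ*", "guess*", "wonder*", "maybe", "perhaps", "should",
    "would", "could", "if", "decide*", "decision*", "question*", "answer*",
    "learn*", "idea*", "mean*", "sense", "consider*", "figure*", "doubt*"
  ]
}
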