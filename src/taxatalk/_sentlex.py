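"""Compact valence lexicon for the sentiment backend.

Word -> mean valence on a [-4, 4] scale, following the convention of
crowd-rated sentiment lexicons for social media.  Coverage targets
high-frequency evaluative vocabulary in news and social posts, including
words common in wildlife/conservation coverage (poaching, rescue,
extinction, thriving, ...).
"""

LEXICON: dict[str, float] = {
    # strongly positive
    "amazing": 2.8, "awesome": 3.1, "beautiful": 2.9, "best": 3.2,
    "brilliant": 2.8, "celebrated": 2.2, "delight": 2.9, "delighted": 2.9,
    "excellent": 2.7, "extraordinary": 2.3, "fantastic": 2.6, "great": 3.1,
    "inspiring": 2.4, "joy": 2.8, "love": 3.2, "loved": 2.9, "magnificent": 2.8,
    "marvelous": 2.6, "outstanding": 2.7, "perfect": 2.7, "spectacular": 2.6,
    "superb": 2.8, "thrilled": 2.8, "triumph": 2.5, "wonderful": 2.7,
    # positive
    "admire": 1.9, "benefit": 1.5, "better": 1.9, "boost": 1.6, "calm": 1.3,
    "capable": 1.3, "care": 1.6, "celebrate": 2.0, "charming": 2.0,
    "cheerful": 2.3, "clean": 1.6, "comfort": 1.6, "confident": 2.2,
    "cute": 2.0, "dedicated": 1.6, "eager": 1.7, "effective": 1.6,
    "encouraging": 1.9, "enjoy": 2.0, "enjoyed": 2.0, "enthusiasm": 2.0,
    "excited": 2.2, "exciting": 2.2, "fascinating": 2.1, "flourish": 2.0,
    "flourishing": 2.0, "fortunate": 1.9, "free": 1.6, "friendly": 2.2,
    "fun": 2.3, "generous": 2.2, "gentle": 1.7, "glad": 2.0, "good": 1.9,
    "grateful": 2.0, "happy": 2.7, "healthy": 1.7, "helpful": 1.8,
    "honor": 1.9, "hope": 1.9, "hopeful": 2.0, "impressive": 2.1,
    "improve": 1.6, "improved": 1.7, "interesting": 1.7, "kind": 1.8,
    "lucky": 2.1, "majestic": 2.1, "nice": 1.8, "optimistic": 1.8,
    "playful": 1.9, "pleased": 1.9, "popular": 1.7, "positive": 1.8,
    "praise": 1.9, "prosper": 2.0, "protect": 1.4, "protected": 1.3,
    "proud": 2.1, "recover": 1.4, "recovery": 1.5, "relief": 1.6,
    "remarkable": 1.8, "rescue": 1.5, "rescued": 1.6, "respect": 1.8,
    "revival": 1.6, "reward": 1.9, "safe": 1.6, "satisfied": 1.8,
    "smile": 2.0, "strong": 1.6, "succeed": 1.9, "success": 2.1,
    "successful": 2.1, "support": 1.6, "surge": 0.9, "thank": 1.7,
    "thanks": 1.9, "thrive": 2.0, "thriving": 2.1, "victory": 2.3,
    "vibrant": 1.9, "warm": 1.4, "welcome": 1.8, "win": 2.4, "winner": 2.4,
    # strongly negative
    "atrocious": -2.8, "awful": -2.7, "catastrophe": -3.0, "catastrophic": -2.9,
    "cruel": -2.8, "dead": -2.7, "death": -2.6, "devastating": -2.9,
    "disaster": -2.6, "disastrous": -2.6, "hate": -2.7, "horrible": -2.7,
    "horrific": -3.0, "killed": -2.9, "kills": -2.6, "massacre": -3.2,
    "murder": -3.0, "slaughter": -3.0, "terrible": -2.5, "tragedy": -2.8,
    "tragic": -2.6, "worst": -3.1,
    # negative
    "abandon": -1.9, "abandoned": -1.9, "afraid": -2.0, "alarm": -1.4,
    "alarming": -1.8, "angry": -2.3, "anxious": -1.7, "attack": -2.1,
    "bad": -2.5, "blame": -1.7, "broken": -1.6, "collapse": -1.9,
    "concern": -1.0, "concerned": -1.1, "conflict": -1.5, "crisis": -2.1,
    "criticism": -1.5, "cruelty": -2.6, "cull": -1.8, "damage": -1.8,
    "danger": -2.0, "dangerous": -2.0, "decline": -1.4, "declining": -1.4,
    "destroy": -2.3, "destroyed": -2.3, "destruction": -2.2, "die": -2.4,
    "died": -2.3, "dying": -2.4, "disease": -1.9, "distress": -1.9,
    "doomed": -2.3, "dread": -2.1, "endangered": -1.4, "extinct": -2.0,
    "extinction": -2.2, "fail": -2.0, "failed": -1.9, "failure": -2.1,
    "fear": -1.9, "fears": -1.8, "fight": -1.5, "frightened": -1.9,
    "grim": -1.9, "harm": -1.9, "harmful": -1.9, "hurt": -2.0,
    "illegal": -1.6, "illness": -1.6, "infected": -1.7, "infection": -1.7,
    "injured": -1.9, "injury": -1.9, "kill": -2.6, "killing": -2.6,
    "loss": -1.6, "lost": -1.4, "miserable": -2.3, "negative": -1.6,
    "outbreak": -1.5, "pain": -2.1, "panic": -2.0, "plague": -2.0,
    "poached": -2.2, "poachers": -2.0, "poaching": -2.1, "poison": -2.2,
    "poisoned": -2.3, "pollution": -1.6, "poor": -1.9, "problem": -1.4,
    "risk": -1.1, "sad": -2.1, "scared": -1.9, "shocking": -1.7,
    "sick": -1.8, "slaughtered": -2.9, "smuggling": -1.8, "sorrow": -2.2,
    "starving": -2.3, "stolen": -1.8, "struggle": -1.5, "struggling": -1.5,
    "suffer": -2.1, "suffering": -2.2, "threat": -1.7, "threaten": -1.7,
    "threatened": -1.6, "toxic": -1.9, "trafficking": -1.9, "ugly": -2.1,
    "victim": -1.8, "violence": -2.4, "violent": -2.4, "warning": -1.2,
    "weak": -1.5, "worried": -1.6, "worry": -1.6, "wounded": -2.0,
}
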