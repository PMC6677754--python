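id,sequence,predicted,active
Helical1,FLWIKLGKLAGAVLKLILGLKKVV,1,1
Helical2,GLWAIAVKAGKVILKLIVFIWIRV,1,0
Helical3,GLLDIAGGNAETLAGHAV,0,0
Helical4,GLFDVIGSQAGGAAPHFLG,0,0
AmphiArc1,KWVKKVHNWLRRWIKVFEALFG,1,1
AmphiArc2,KIFKKFKTIIKKVWRIFGRF,1,1
AmphiArc3,AFRHSVKEELNYIRRRLERFPNRL,0,0
AmphiArc4,RIENGLRKRLQSIYRHLEE,0,0
Gradient1,KWVRIWIKVLRGLFVWVWFF,1,0
Gradient2,AWLKRIKKFLKALFWVWVW,1,1
Gradient3,KVVDNFENILII,0,0
Gradient4,RVNAAIPNIIV,0,0
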