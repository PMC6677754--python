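>Helical1
FLWIKLGKLAGAVLKLILGLKKVV
>Helical2
GLWAIAVKAGKVILKLIVFIWIRV
>Helical3
GLLDIAGGNAETLAGHAV
>Helical4
GLFDVIGSQAGGAAPHFLG
>AmphiArc1
KWVKKVHNWLRRWIKVFEALFG
>AmphiArc2
KIFKKFKTIIKKVWRIFGRF
>AmphiArc3
AFRHSVKEELNYIRRRLERFPNRL
>AmphiArc4
RIENGLRKRLQSIYRHLEE
>Gradient1
KWVRIWIKVLRGLFVWVWFF
>Gradient2
AWLKRIKKFLKALFWVWVW
>Gradient3
KVVDNFENILII
>Gradient4
RVNAAIPNIIV
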