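# Common US female given names, roughly frequency-ranked
mary
patricia
jennifer
linda
elizabeth
barbara
susan
jessica
sarah
karen
lisa
nancy
betty
margaret
sandra
ashley
kimberly
emily
donna
michelle
carol
amanda
dorothy
melissa
deborah
stephanie
rebecca
sharon
laura
cynthia
kathleen
amy
angela
shirley
anna
brenda
pamela
emma
nicole
helen
samantha
katherine
christine
debra
rachel
carolyn
janet
catherine
maria
heather
diane
ruth
julie
olivia
joyce
virginia
victoria
kelly
lauren
christina
joan
evelyn
judith
megan
andrea
cheryl
hannah
jacqueline
martha
gloria
teresa
ann
sara
madison
frances
kathryn
janice
jean
alice
doris
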