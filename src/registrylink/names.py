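"""Fixed name pools for the synthetic registry generator.

Common US given names and surnames; the nickname map drives the
nickname-substitution branch of the identity error model (either direction:
a registry may hold "William" where another holds "Bill").
"""

FIRST_NAMES_MALE: tuple[str, ...] = (
    "James", "John", "Robert", "Michael", "William", "David", "Richard", "Joseph",
    "Thomas", "Charles", "Christopher", "Daniel", "Matthew", "Anthony", "Donald",
    "Mark", "Paul", "Steven", "Andrew", "Kenneth", "Joshua", "Kevin", "Brian",
    "George", "Edward", "Ronald", "Timothy", "Jason", "Jeffrey", "Ryan", "Jacob",
    "Gary", "Nicholas", "Eric", "Jonathan", "Stephen", "Larry", "Justin", "Scott",
    "Brandon", "Benjamin", "Samuel", "Gregory", "Frank", "Alexander", "Raymond",
    "Patrick", "Jack", "Dennis", "Jerry", "Tyler", "Aaron", "Jose", "Adam",
    "Henry", "Nathan", "Douglas", "Zachary", "Peter", "Kyle", "Walter", "Ethan",
    "Jeremy", "Harold", "Keith", "Christian", "Roger", "Noah", "Gerald", "Carl",
    "Terry", "Sean", "Austin", "Arthur", "Lawrence", "Jesse", "Dylan", "Bryan",
    "Joe", "Jordan", "Billy", "Bruce", "Albert", "Willie", "Gabriel", "Logan",
    "Alan", "Juan", "Wayne", "Roy", "Ralph", "Randy", "Eugene", "Vincent",
    "Russell", "Elijah", "Louis", "Bobby", "Philip", "Johnny", "Marcus",
)

FIRST_NAMES_FEMALE: tuple[str, ...] = (
    "Mary", "Patricia", "Jennifer", "Linda", "Elizabeth", "Barbara", "Susan",
    "Jessica", "Sarah", "Karen", "Nancy", "Lisa", "Betty", "Margaret", "Sandra",
    "Ashley", "Kimberly", "Emily", "Donna", "Michelle", "Dorothy", "Carol",
    "Amanda", "Melissa", "Deborah", "Stephanie", "Rebecca", "Sharon", "Laura",
    "Cynthia", "Kathleen", "Amy", "Shirley", "Angela", "Helen", "Anna", "Brenda",
    "Pamela", "Nicole", "Emma", "Samantha", "Katherine", "Christine", "Debra",
    "Rachel", "Catherine", "Carolyn", "Janet", "Ruth", "Maria", "Heather",
    "Diane", "Virginia", "Julie", "Joyce", "Victoria", "Olivia", "Kelly",
    "Christina", "Lauren", "Joan", "Evelyn", "Judith", "Megan", "Cheryl",
    "Andrea", "Hannah", "Martha", "Jacqueline", "Frances", "Gloria", "Ann",
    "Teresa", "Kathryn", "Sara", "Janice", "Jean", "Alice", "Madison", "Doris",
    "Abigail", "Julia", "Judy", "Grace", "Denise", "Amber", "Marilyn", "Beverly",
    "Danielle", "Theresa", "Sophia", "Marie", "Diana", "Brittany", "Natalie",
    "Isabella", "Charlotte", "Rose", "Alexis", "Kayla",
)

LAST_NAMES: tuple[str, ...] = (
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green", "Adams",
    "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell", "Carter",
    "Roberts", "Gomez", "Phillips", "Evans", "Turner", "Diaz", "Parker",
    "Cruz", "Edwards", "Collins", "Reyes", "Stewart", "Morris", "Morales",
    "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan", "Cooper",
    "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos", "Kim", "Cox",
    "Ward", "Richardson", "Watson", "Brooks", "Chavez", "Wood", "James",
    "Bennett", "Gray", "Mendoza", "Ruiz", "Hughes", "Price", "Alvarez",
    "Castillo", "Sanders", "Patel", "Myers", "Long", "Ross", "Foster",
    "Jimenez", "Powell", "Jenkins", "Perry", "Russell", "Sullivan", "Bell",
    "Coleman", "Butler", "Henderson", "Barnes", "Gonzales", "Fisher",
    "Vasquez", "Simmons", "Romero", "Jordan", "Patterson", "Alexander",
    "Hamilton", "Graham", "Reynolds", "Griffin", "Wallace", "Moreno", "West",
    "Cole", "Hayes", "Bryant", "Herrera", "Gibson", "Ellis", "Tran", "Medina",
    "Aguilar", "Stevens", "Murray", "Ford", "Castro", "Marshall", "Owens",
    "Harrison", "Fernandez", "McDonald", "Woods", "Washington", "Kennedy",
    "Wells", "Vargas", "Henry", "Chen", "Freeman", "Webb", "Tucker", "Guzman",
    "Burns", "Crawford", "Olson", "Simpson", "Porter", "Hunter", "Gordon",
    "Mendez", "Silva", "Shaw", "Snyder", "Mason", "Dixon", "Munoz", "Hunt",
    "Hicks", "Holmes", "Palmer", "Wagner", "Black", "Robertson", "Boyd",
    "Rose", "Stone", "Salazar", "Fox", "Warren", "Mills", "Meyer", "Rice",
    "Schmidt", "Garza", "Daniels", "Ferguson", "Nichols", "Stephens", "Soto",
    "Weaver", "Ryan", "Gardner", "Payne", "Grant", "Dunn", "Kelley", "Spencer",
    "Hawkins", "Arnold", "Pierce", "Vazquez", "Hansen", "Peters", "Santos",
)

#: canonical-name -> nickname (substitution may run either direction)
NICKNAMES: dict[str, str] = {
    "William": "Bill", "Robert": "Bob", "Richard": "Rick", "James": "Jim",
    "John": "Jack", "Michael": "Mike", "Joseph": "Joe", "Thomas": "Tom",
    "Charles": "Chuck", "Christopher": "Chris", "Daniel": "Dan",
    "Matthew": "Matt", "Anthony": "Tony", "Donald": "Don", "Steven": "Steve",
    "Andrew": "Andy", "Kenneth": "Ken", "Joshua": "Josh", "Edward": "Ed",
    "Ronald": "Ron", "Timothy": "Tim", "Jeffrey": "Jeff", "Jacob": "Jake",
    "Nicholas": "Nick", "Jonathan": "Jon", "Benjamin": "Ben", "Samuel": "Sam",
    "Gregory": "Greg", "Alexander": "Alex", "Raymond": "Ray", "Patrick": "Pat",
    "Dennis": "Denny", "Zachary": "Zach", "Peter": "Pete", "Walter": "Walt",
    "Jeremy": "Jerry", "Gerald": "Gerry", "Lawrence": "Larry", "Eugene": "Gene",
    "Russell": "Russ", "Louis": "Lou", "Philip": "Phil", "Vincent": "Vince",
    "Elizabeth": "Beth", "Patricia": "Pat", "Jennifer": "Jen", "Barbara": "Barb",
    "Susan": "Sue", "Jessica": "Jess", "Kimberly": "Kim", "Margaret": "Peggy",
    "Deborah": "Deb", "Stephanie": "Steph", "Rebecca": "Becky",
    "Kathleen": "Kathy", "Angela": "Angie", "Pamela": "Pam", "Samantha": "Sam",
    "Katherine": "Kate", "Christine": "Chris", "Rachel": "Rae",
    "Catherine": "Cathy", "Victoria": "Vicky", "Christina": "Tina",
    "Judith": "Judy", "Jacqueline": "Jackie", "Frances": "Fran",
    "Teresa": "Terry", "Abigail": "Abby", "Julia": "Julie", "Denise": "Dee",
    "Danielle": "Dani", "Theresa": "Tess", "Brittany": "Britt",
    "Natalie": "Nat", "Isabella": "Bella", "Charlotte": "Lottie",
    "Alexis": "Lexi", "Madison": "Maddie", "Dorothy": "Dot", "Sandra": "Sandy",
    "Cynthia": "Cindy", "Melissa": "Mel", "Amanda": "Mandy",
}

#: reverse map nickname -> canonical, for substitution in either direction
NICKNAMES_REVERSE: dict[str, str] = {v: k for k, v in NICKNAMES.items()}
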